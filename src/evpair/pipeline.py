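"""End-to-end per-protein-pair pipeline.

Stages: read the two monomer alignments, pair them species by species,
apply the concatenation quality-control guards, infer couplings by PLM,
derive ranked EC scores and residue features, optionally compare against
structures and score with trained models, and optionally export docking
restraints.  Every numeric threshold lives in :class:`PipelineConfig`
with the method's default; a failed guard produces a machine-readable
status instead of a crash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evscores, structmap
from .errors import ConfigurationError, DegenerateInputError
from .msa import (
    DEFAULT_ALPHABET,
    MSA,
    column_stats,
    compute_weights,
    filter_gappy_rows,
    monomer_eligibility,
    read_alignment,
    write_fasta,
)
from .pairing import (
    PairedMSA,
    annotate_species,
    qc_concatenated,
    read_annotation_tsv,
    reciprocal_concatenate,
)
from .plm import apc, build_ec_table, fit_plm, frobenius_scores, inter_zscores

logger = logging.getLogger("evpair")

STATUS_OK = "ok"
STATUS_INELIGIBLE = "ineligible_monomer"
STATUS_DEGENERATE = "degenerate"


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a per-pair run.

    Defaults are the method's standard operating point: 80% identity
    reweighting, 50% gap filters, 80% column coverage, 90% query-paralog
    exclusion, monomer N_eff/L >= 2.5 and concatenated N_eff/L >= 0.2,
    5-residue diagonal exclusion, 8 A contact definition, top-10 feature
    rows and top-5 restraint pairs.
    """

    alignment_a: str | None = None
    alignment_b: str | None = None
    alignment_format: str = "fasta"
    query_id_a: str | None = None
    query_id_b: str | None = None
    paired_input: str | None = None
    L1: int | None = None

    alphabet: str = DEFAULT_ALPHABET
    theta: float = 0.8
    row_max_gap: float = 0.5
    col_max_gap: float = 0.5
    coverage_min_fraction: float = 0.8
    paralog_exclusion: float = 0.9
    monomer_min_neff_per_l: float = 2.5
    concat_min_neff_per_l: float = 0.2
    enforce_monomer_eligibility: bool = True
    min_sequence_separation: int = 5
    contact_cutoff: float = 8.0
    n_top_features: int = 10
    n_top_restraints: int = 5

    lambda_h: float = 0.01
    lambda_base: float = 0.01
    plm_maxiter: int = 500

    annotations_a: str | None = None
    annotations_b: str | None = None
    structure_hits_a: str | None = None
    structure_hits_b: str | None = None
    residue_model: str | None = None
    interaction_model: str | None = None
    structures: list[str] = field(default_factory=list)
    mapping: str | None = None
    write_restraints: bool = False

    seed: int = 0
    output_dir: str = "evpair_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    status: str
    reason: str = ""
    outputs: dict = field(default_factory=dict)
    qc: dict | None = None
    interaction_probability: float | None = None


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _load_annotations(path: str | None, protein_id: str) -> list[str]:
    if path is None:
        return []
    table = read_annotation_tsv(path)
    return table.get(protein_id, [])


def _prepare_paired(config: PipelineConfig) -> tuple[PairedMSA, str | None]:
    """Returns (paired alignment, failure status or None)."""
    if config.paired_input:
        if config.L1 is None:
            raise ConfigurationError("paired_input requires L1")
        m = read_alignment(config.paired_input, config.alignment_format)
        L2 = m.L - config.L1
        if L2 <= 0:
            raise ConfigurationError("L1 exceeds alignment width")
        return PairedMSA(msa=m, L1=config.L1, L2=L2, pairs=[]), None

    if not (config.alignment_a and config.alignment_b):
        raise ConfigurationError("need alignment_a and alignment_b (or paired_input)")
    msa_a = annotate_species(
        read_alignment(config.alignment_a, config.alignment_format, config.query_id_a)
    )
    msa_b = annotate_species(
        read_alignment(config.alignment_b, config.alignment_format, config.query_id_b)
    )
    if config.enforce_monomer_eligibility:
        for name, m in (("A", msa_a), ("B", msa_b)):
            mw = compute_weights(m, theta=config.theta)
            if not monomer_eligibility(mw, config.monomer_min_neff_per_l):
                logger.info("monomer %s ineligible (N_eff/L or coverage)", name)
                return None, f"{STATUS_INELIGIBLE}:{name}"
    paired = reciprocal_concatenate(msa_a, msa_b, config.paralog_exclusion)
    return paired, None


def run_pair(config: PipelineConfig) -> PipelineResult:
    """Run the full per-pair analysis; never raises on QC failure."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    try:
        prepared, fail = _prepare_paired(config)
    except DegenerateInputError as exc:
        return PipelineResult(status=STATUS_DEGENERATE, reason=str(exc))
    if fail is not None:
        return PipelineResult(status=fail, reason="monomer alignment ineligible")
    paired = prepared

    m = filter_gappy_rows(paired.msa, config.row_max_gap)
    m = compute_weights(m, theta=config.theta)
    paired = PairedMSA(msa=m, L1=paired.L1, L2=paired.L2, pairs=paired.pairs)
    write_fasta(m, out / "paired.fasta")
    if paired.pairs:
        _csv(
            pd.DataFrame(
                paired.pairs, columns=["species", "id_a", "id_b", "identity_a", "identity_b"]
            ),
            out / "pairs.csv",
        )
    logger.info("concatenated alignment: %d rows, L=%d, N_eff/L=%.3f",
                m.n_rows, m.L, m.n_eff / m.L)

    qid_a = config.query_id_a or (paired.pairs[0][1] if paired.pairs else "A")
    qid_b = config.query_id_b or (paired.pairs[0][2] if paired.pairs else "B")
    qc = qc_concatenated(
        paired,
        annotations_a=_load_annotations(config.annotations_a, qid_a),
        annotations_b=_load_annotations(config.annotations_b, qid_b),
        structure_hits_a=_load_annotations(config.structure_hits_a, qid_a),
        structure_hits_b=_load_annotations(config.structure_hits_b, qid_b),
        min_neff_per_l=config.concat_min_neff_per_l,
    )

    def _qc_out(report, table=None) -> None:
        with open(out / "qc.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)

    pre_guards = qc.failed_guards()
    if pre_guards:
        _qc_out(qc)
        return PipelineResult(
            status=f"qc_failed:{pre_guards[0]}", reason=",".join(pre_guards), qc=qc.as_dict()
        )

    # --- couplings ---
    t1 = time.time()
    model = fit_plm(
        paired,
        lambda_h=config.lambda_h,
        lambda_base=config.lambda_base,
        alphabet=config.alphabet,
        theta=config.theta,
        maxiter=config.plm_maxiter,
    )
    logger.info("PLM fit in %.1fs (L=%d, q=%d)", time.time() - t1, model.L, model.q)
    fn = frobenius_scores(model)
    cn = apc(fn)
    table = build_ec_table(
        cn, paired.L1, paired.L2, m.n_eff, fn_matrix=fn,
        min_sequence_separation=config.min_sequence_separation,
    )
    table = inter_zscores(table)
    table = evscores.evcomplex_transform(table)

    qc = qc_concatenated(
        paired,
        annotations_a=_load_annotations(config.annotations_a, qid_a),
        annotations_b=_load_annotations(config.annotations_b, qid_b),
        structure_hits_a=_load_annotations(config.structure_hits_a, qid_a),
        structure_hits_b=_load_annotations(config.structure_hits_b, qid_b),
        ec_table=table,
        min_neff_per_l=config.concat_min_neff_per_l,
    )
    _qc_out(qc)
    _csv(table, out / "ec_table.csv")
    if not qc.eligible:
        guard = qc.failed_guards()[0]
        return PipelineResult(status=f"qc_failed:{guard}", reason=guard, qc=qc.as_dict(),
                              outputs={"ec_table": str(out / "ec_table.csv")})

    # --- features ---
    cons = column_stats(m).conservation
    enrich = evscores.intra_enrichment(table)

    rsa_vec = None
    labels = None
    intra_status = None
    dmap = None
    if config.structures and config.mapping:
        structures = [structmap.load_structure(p) for p in config.structures]
        mapping = structmap.read_mapping_tsv(config.mapping)
        dmap = structmap.min_distance_map(structures, mapping, L1=paired.L1)
        all_labels = structmap.contact_labels(dmap, cutoff=config.contact_cutoff)
        labels = all_labels
        intra_status = {
            k: v for k, v in all_labels.items()
            if v is not None and ((k[0] <= paired.L1) == (k[1] <= paired.L1))
        }
        prof = structmap.relative_sasa(structures)
        rel = prof.rel_by_residue()
        rsa_vec = np.full(m.L, np.nan)
        for pos, key in mapping.items():
            if key in rel:
                rsa_vec[pos - 1] = rel[key]

    features = evscores.build_residue_features(
        table, cons, enrich, rsa=rsa_vec,
        intra_contact_status=intra_status, labels=labels,
        n_top=config.n_top_features,
    )
    _csv(features, out / "features.csv")

    result = PipelineResult(status=STATUS_OK, qc=qc.as_dict())
    result.outputs = {
        "paired": str(out / "paired.fasta"),
        "qc": str(out / "qc.json"),
        "ec_table": str(out / "ec_table.csv"),
        "features": str(out / "features.csv"),
    }

    if dmap is not None:
        report = {
            "inter_precision_top10": evscores_precision(table, dmap, config.contact_cutoff),
            "interface_pairs_lt5A": structmap.interface_pair_count(dmap, cutoff=5.0),
        }
        with open(out / "structure_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        result.outputs["structure_report"] = str(out / "structure_report.json")

    # --- model scoring ---
    residue_probs = None
    if config.residue_model:
        rmodel = evscores.LogisticModel.load(config.residue_model)
        feats = features.copy()
        for c in rmodel.feature_names:
            feats[c] = feats[c].fillna(0.0)
        residue_probs = rmodel.predict_proba(feats)
        scored = features.copy()
        scored["residue_prob"] = residue_probs
        scored["row_type"] = "ec"
        summary = {c: np.nan for c in scored.columns}
        summary.update({"row_type": "summary"})
        if config.interaction_model:
            imodel = evscores.LogisticModel.load(config.interaction_model)
            inter_score = evscores.score_protein_interaction(
                residue_probs, float(features["inter_relative_rank"].iloc[0]), imodel
            )
            summary["residue_prob"] = inter_score.probability
            result.interaction_probability = inter_score.probability
        scored = pd.concat([scored, pd.DataFrame([summary])], ignore_index=True)
        _csv(scored, out / "scores.csv")
        result.outputs["scores"] = str(out / "scores.csv")

    if config.write_restraints:
        if not config.mapping:
            raise ConfigurationError("restraint export requires a residue mapping")
        mapping = structmap.read_mapping_tsv(config.mapping)
        query = m.seqs[m.query_index]
        residue_map = {
            pos: (key[0], key[1], query[pos - 1]) for pos, key in mapping.items()
        }
        inter = table[table["is_inter"]].nsmallest(len(table), "rank")
        mode_scores = {}
        if residue_probs is not None:
            mode_scores["structure-free"] = np.asarray(residue_probs)
        else:
            mode_scores["cn"] = inter["cn"].to_numpy()[: config.n_top_features]
        text, skipped = evscores.export_restraints(
            table, mode_scores, residue_map, n_top=config.n_top_restraints
        )
        (out / "restraints.tbl").write_text(text)
        if skipped:
            logger.warning("%d restraint pair(s) skipped: unmappable residues", skipped)
        result.outputs["restraints"] = str(out / "restraints.tbl")

    logger.info("pipeline finished in %.1fs (status=%s)", time.time() - t0, result.status)
    return result


def evscores_precision(table: pd.DataFrame, dmap, cutoff: float) -> float:
    inter = table[table["is_inter"]]
    return structmap.ec_precision(inter, dmap, cutoff=cutoff, k=evscores.N_TOP_INTER)
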