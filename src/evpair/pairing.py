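"""Species-aware concatenation of two monomer alignments.

Coevolution between two proteins can only be measured on sequence pairs
that actually co-occur in one genome.  This module pairs the two monomer
alignments species by species: within each species the member closest to
the query is taken as the putative ortholog, near-duplicate paralogs of
the query genome are excluded, and a species contributes a row to the
concatenated alignment only when the choice is consistent in both
alignments (reciprocal highest identity).  Quality-control guards reject
concatenations that are likely homology artifacts rather than genuine
interactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DegenerateInputError
from .msa import AMINO_ACIDS, GAP, MSA, column_stats, identities_to_query, pairwise_identity

_MNEMONIC_RE = re.compile(r"^[A-Z0-9]{1,10}$")


@dataclass
class PairedMSA:
    """Concatenation of two monomer alignments, one row per species."""

    msa: MSA
    L1: int
    L2: int
    #: (species, id_a, id_b, identity_a, identity_b) per concatenated row
    pairs: list[tuple[str, str, str, float, float]]

    def segment_of(self, pos: int) -> str:
        """'A' or 'B' for a 0-based concatenated column index."""
        return "A" if pos < self.L1 else "B"


@dataclass
class QCReport:
    neff_over_l: float
    coverage_pass: bool
    shared_domain: bool
    shared_structure_hit: bool
    diagonal_artifact: bool
    nonstandard_aa: bool

    @property
    def eligible(self) -> bool:
        return (
            self.coverage_pass
            and self.neff_over_l >= 0.2
            and not self.shared_domain
            and not self.shared_structure_hit
            and not self.diagonal_artifact
            and not self.nonstandard_aa
        )

    def failed_guards(self) -> list[str]:
        out = []
        if not self.coverage_pass:
            out.append("coverage")
        if self.neff_over_l < 0.2:
            out.append("neff")
        if self.shared_domain:
            out.append("shared_domain")
        if self.shared_structure_hit:
            out.append("shared_structure_hit")
        if self.diagonal_artifact:
            out.append("diagonal_artifact")
        if self.nonstandard_aa:
            out.append("nonstandard_aa")
        return out

    def as_dict(self) -> dict:
        d = {
            "neff_over_l": self.neff_over_l,
            "coverage_pass": self.coverage_pass,
            "shared_domain": self.shared_domain,
            "shared_structure_hit": self.shared_structure_hit,
            "diagonal_artifact": self.diagonal_artifact,
            "nonstandard_aa": self.nonstandard_aa,
            "eligible": self.eligible,
        }
        return d


def parse_species(header: str) -> str | None:
    """Extract a species tag from a UniProt-style header.

    Tries, in order: the mnemonic after '_' in the identifier token
    (``sp|P0A8M3|THRS_ECOLI`` -> ``ECOLI``), an ``OX=`` taxon id, and an
    ``OS=`` organism name.  Returns ``None`` when nothing is found.
    """
    if not header:
        return None
    token = header.split()[0]
    token = token.split("|")[-1].split("/")[0]  # drop uniprot db prefixes and ranges
    if "_" in token:
        tag = token.rsplit("_", 1)[1]
        if _MNEMONIC_RE.match(tag):
            return tag
    m = re.search(r"\bOX=(\d+)", header)
    if m:
        return m.group(1)
    m = re.search(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)", header)
    if m:
        return m.group(1).strip()
    return None


def annotate_species(msa: MSA) -> MSA:
    """Fill the per-row species labels from the sequence headers."""
    msa.species = [parse_species(h) for h in msa.ids]
    return msa


def best_hit_per_species(msa: MSA, exclude_rows: set[int] | None = None) -> dict[str, int]:
    """Per species, the row with highest identity to the query.

    Ties break to the lowest row index.  Rows without a species label and
    rows in ``exclude_rows`` are skipped.
    """
    exclude_rows = exclude_rows or set()
    ident = identities_to_query(msa)
    best: dict[str, int] = {}
    for r in range(msa.n_rows):
        sp = msa.species[r]
        if sp is None or r in exclude_rows:
            continue
        if sp not in best or ident[r] > ident[best[sp]]:
            best[sp] = r
    return best


def exclude_query_paralogs(msa: MSA, threshold: float = 0.9) -> set[int]:
    """Rows of the query's species whose identity to the query exceeds
    ``threshold`` (near-duplicate paralogs); the query row itself is kept."""
    qsp = msa.species[msa.query_index]
    if qsp is None:
        return set()
    ident = identities_to_query(msa)
    return {
        r
        for r in range(msa.n_rows)
        if r != msa.query_index and msa.species[r] == qsp and ident[r] > threshold
    }


def _query_species_paralog_rows(msa: MSA, excluded: set[int]) -> list[int]:
    qsp = msa.species[msa.query_index]
    return [
        r
        for r in range(msa.n_rows)
        if r != msa.query_index and msa.species[r] == qsp and r not in excluded
    ]


def reciprocal_concatenate(
    msa_a: MSA, msa_b: MSA, paralog_threshold: float = 0.9
) -> PairedMSA:
    """Concatenate two monomer alignments by reciprocal highest identity.

    For every species present in both alignments, the member closest to
    each query is selected; the pair is kept only if, in both alignments,
    the candidate is closer to the query than to any remaining paralog of
    the query genome.  The two query rows themselves always form row 0.
    """
    if all(s is None for s in msa_a.species) or all(s is None for s in msa_b.species):
        raise DegenerateInputError("species labels missing; run annotate_species first")

    ident_a = identities_to_query(msa_a)
    ident_b = identities_to_query(msa_b)
    excl_a = exclude_query_paralogs(msa_a, paralog_threshold)
    excl_b = exclude_query_paralogs(msa_b, paralog_threshold)
    best_a = best_hit_per_species(msa_a, exclude_rows=excl_a)
    best_b = best_hit_per_species(msa_b, exclude_rows=excl_b)
    par_a = _query_species_paralog_rows(msa_a, excl_a)
    par_b = _query_species_paralog_rows(msa_b, excl_b)

    def _reciprocal_ok(msa: MSA, row: int, ident_to_query: float, paralogs: list[int]) -> bool:
        cand = msa.seqs[row]
        for p in paralogs:
            if pairwise_identity(cand, msa.seqs[p]) > ident_to_query:
                return False
        return True

    qsp = msa_a.species[msa_a.query_index]
    qa, qb = msa_a.query_index, msa_b.query_index
    ids = [f"{qsp or 'QUERY'}|{msa_a.ids[qa]}|{msa_b.ids[qb]}"]
    seqs = [msa_a.seqs[qa] + msa_b.seqs[qb]]
    species: list[str | None] = [qsp]
    pairs: list[tuple[str, str, str, float, float]] = [
        (qsp or "QUERY", msa_a.ids[qa], msa_b.ids[qb], 1.0, 1.0)
    ]

    shared = sorted(set(best_a) & set(best_b))
    for sp in shared:
        if sp == qsp:
            continue  # the query pair already represents the query species
        ra, rb = best_a[sp], best_b[sp]
        if ra == qa or rb == qb:
            continue
        if not _reciprocal_ok(msa_a, ra, float(ident_a[ra]), par_a):
            continue
        if not _reciprocal_ok(msa_b, rb, float(ident_b[rb]), par_b):
            continue
        ids.append(f"{sp}|{msa_a.ids[ra]}|{msa_b.ids[rb]}")
        seqs.append(msa_a.seqs[ra] + msa_b.seqs[rb])
        species.append(sp)
        pairs.append((sp, msa_a.ids[ra], msa_b.ids[rb], float(ident_a[ra]), float(ident_b[rb])))

    if len(seqs) < 2:
        raise DegenerateInputError(
            f"only {len(seqs)} concatenated row(s); cannot analyze coevolution"
        )
    paired = MSA(ids=ids, seqs=seqs, species=species, query_index=0)
    return PairedMSA(msa=paired, L1=msa_a.L, L2=msa_b.L, pairs=pairs)


def _split_query(paired: PairedMSA) -> tuple[str, str]:
    q = paired.msa.seqs[paired.msa.query_index]
    return q[: paired.L1], q[paired.L1 :]


def qc_concatenated(
    paired: PairedMSA,
    annotations_a: list[str] | None = None,
    annotations_b: list[str] | None = None,
    structure_hits_a: list[str] | None = None,
    structure_hits_b: list[str] | None = None,
    ec_table=None,
    min_neff_per_l: float = 0.2,
) -> QCReport:
    """All quality-control guards on a concatenated alignment.

    Domain and structure-hit annotations are externally supplied id lists
    (PFAM accessions; ``pdbid_chain`` strings).  The diagonal-coevolution
    guard needs an EC table and is skipped (reported False) without one.
    Weights must be computed on ``paired.msa``.
    """
    m = paired.msa
    if m.n_eff is None:
        raise DegenerateInputError("weights not computed on concatenated alignment")
    stats = column_stats(m)

    shared_domain = bool(set(annotations_a or []) & set(annotations_b or []))
    shared_structure = bool(set(structure_hits_a or []) & set(structure_hits_b or []))

    diagonal = False
    if ec_table is not None:
        from .evscores import diagonal_artifact_check

        diagonal = diagonal_artifact_check(ec_table)

    qa, qb = _split_query(paired)
    allowed = set(AMINO_ACIDS + GAP)
    nonstandard = any(c not in allowed for c in qa + qb)

    return QCReport(
        neff_over_l=m.n_eff / m.L,
        coverage_pass=stats.coverage_pass,
        shared_domain=shared_domain,
        shared_structure_hit=shared_structure,
        diagonal_artifact=diagonal,
        nonstandard_aa=nonstandard,
    )


def read_annotation_tsv(path) -> dict[str, list[str]]:
    """2-column TSV (protein id, annotation id) -> id -> annotation list."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, ann = line.split("\t")[:2]
            out.setdefault(pid, []).append(ann)
    return out
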