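"""Candidate specificity scoring and per-oligo mismatch profiling.

Two complementary views of how well a primer/probe set discriminates its
target from congeneric controls (CONs):

* **exact-match scoring** — for each candidate set, count how many of its
  three oligos occur somewhere in a CON barcode with zero mismatches
  (full-length, ungapped, either strand). Summed over the CON panel, the
  lowest-scoring candidate is the most species-specific; ties go to the
  better design-software rank.
* **mismatch profiling** — for a chosen assay, find each oligo's
  minimum-mismatch ungapped placement on a template and report the
  per-oligo and total base-pair differences (the in-silico specificity
  evidence: targets profile to 0 everywhere, CONs accumulate differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seq import (
    AssayDefinition,
    IUPACSequence,
    Oligo,
    SequenceError,
    offset_mismatch_counts,
    reverse_complement,
)


@dataclass(frozen=True)
class CandidateSet:
    """One design-software candidate: rank + forward/reverse/probe oligos."""

    species: str
    rank: int
    forward: Oligo
    reverse: Oligo
    probe: Oligo

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("candidate rank must be >= 1")

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.forward, self.reverse, self.probe)


@dataclass
class SpecificityScore:
    candidate_rank: int
    per_con: dict[str, int]
    total: int = 0

    def __post_init__(self) -> None:
        self.total = sum(self.per_con.values())


@dataclass
class MismatchProfile:
    """Per-oligo minimum mismatch counts of an assay against one template."""

    con_name: str
    forward_mismatches: int
    reverse_mismatches: int
    probe_mismatches: int
    footprints: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.forward_mismatches + self.reverse_mismatches + self.probe_mismatches


def _min_mismatch_placement(
    oligo_bases: str, template: IUPACSequence, strands: Sequence[str]
) -> tuple[int, tuple[int, int], str]:
    """Best ungapped placement of an oligo over all offsets and given strands.

    Returns (mismatches, (start, end) plus-strand interval, strand). Ties
    resolve to the smallest plus-strand offset, '+' before '-'.
    """
    tpl = template.bases
    L = len(oligo_bases)
    if len(tpl) < L:
        raise SequenceError(
            f"template {template.id!r} shorter than oligo ({len(tpl)} < {L})"
        )
    rc = reverse_complement(IUPACSequence(id="o", bases=oligo_bases)).bases
    best: tuple[int, int, int] | None = None  # (mm, start, strand_order)
    for strand_order, (strand, query) in enumerate((("+", oligo_bases), ("-", rc))):
        if strand not in strands:
            continue
        counts = offset_mismatch_counts(query, tpl)
        start = int(counts.argmin())  # argmin takes the smallest offset on ties
        cand = (int(counts[start]), start, strand_order)
        if best is None or cand < best:
            best = cand
    mm, start, strand_order = best
    return mm, (start, start + L), "+-"[strand_order]


# binding-strand convention for amplification (see the in-silico PCR
# module): forward primer on the plus strand, reverse primer on the minus
# strand, probe on either. Mismatch PROFILING is orientation-agnostic —
# templates may be submitted in either orientation, so every oligo is
# scanned on both strands and the better placement reported; the footprint
# records which strand it was.
_ROLE_STRANDS = {"forward": ("+",), "reverse": ("-",), "probe": ("+", "-")}


def exact_match_score(candidate: CandidateSet, con_seq: IUPACSequence) -> int:
    """0–3: how many of the candidate's oligos occur exactly in ``con_seq``.

    An oligo counts if it has a zero-mismatch full-length ungapped
    occurrence on either strand; degenerate oligo bases match any
    compatible template base.
    """
    score = 0
    for oligo in candidate.oligos:
        mm, _, _ = _min_mismatch_placement(oligo.bases.bases, con_seq, ("+", "-"))
        if mm == 0:
            score += 1
    return score


def method1_rank(
    candidates: Sequence[CandidateSet], con_panel: Sequence[IUPACSequence]
) -> list[tuple[CandidateSet, SpecificityScore]]:
    """Rank candidates by summed exact-match score over a CON panel.

    Lowest total wins (most species-specific); equal totals break by the
    candidate's design-software rank (best rank first). The first element
    of the result is the selected set.
    """
    if not candidates:
        raise ValueError("no candidate sets supplied")
    if not con_panel:
        raise ValueError("empty CON panel")
    ranks = [c.rank for c in candidates]
    if len(set(ranks)) != len(ranks):
        raise ValueError("candidate ranks must be unique")
    scored = []
    for cand in candidates:
        per_con = {seq.id: exact_match_score(cand, seq) for seq in con_panel}
        scored.append((cand, SpecificityScore(candidate_rank=cand.rank, per_con=per_con)))
    scored.sort(key=lambda cs: (cs[1].total, cs[0].rank))
    return scored


def mismatch_profile(assay: AssayDefinition, template: IUPACSequence) -> MismatchProfile:
    """Minimum-mismatch profile of an assay's three oligos on a template.

    Each oligo is scanned over every ungapped offset on its binding
    strand(s); the reported footprint is the minimum-mismatch placement
    (smallest offset on ties). Footprint intervals are 0-based half-open
    plus-strand coordinates.
    """
    counts: dict[str, int] = {}
    footprints = []
    for oligo in assay.oligos:
        mm, interval, strand = _min_mismatch_placement(
            oligo.bases.bases, template, ("+", "-")
        )
        counts[oligo.role] = mm
        footprints.append((oligo.role, interval, strand))
    return MismatchProfile(
        con_name=template.id,
        forward_mismatches=counts["forward"],
        reverse_mismatches=counts["reverse"],
        probe_mismatches=counts["probe"],
        footprints=footprints,
    )


def profile_table(
    assay: AssayDefinition, templates: Iterable[IUPACSequence]
):
    """Mismatch profiles for many templates as a tidy DataFrame
    (rows = species, columns = per-oligo and total mismatches)."""
    import pandas as pd

    rows = []
    for tpl in templates:
        p = mismatch_profile(assay, tpl)
        rows.append(
            {
                "species": p.con_name,
                "forward_mismatches": p.forward_mismatches,
                "reverse_mismatches": p.reverse_mismatches,
                "probe_mismatches": p.probe_mismatches,
                "total": p.total,
            }
        )
    return pd.DataFrame(rows)


def select_by_cq(cq_by_method: dict[str, float]) -> str:
    """Pick the design method whose screened primer pair gave the lowest Cq.

    Trivial argmin with lexicographic tie-break; the Cq values themselves
    are laboratory measurements supplied by the user.
    """
    if not cq_by_method:
        raise ValueError("no Cq values supplied")
    return min(sorted(cq_by_method), key=lambda k: cq_by_method[k])
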