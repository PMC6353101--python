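"""In-silico PCR: binding-site search and amplicon prediction.

Given an assay (forward primer, reverse primer, hydrolysis probe) and a
template, enumerate every ungapped binding site within a mismatch
tolerance, pair forward/reverse sites into candidate amplicons inside a
product-size window, and mark a prediction valid only when the probe also
binds strictly between the two primer footprints — the three-oligo
specificity requirement that makes probe-based qPCR calls trustworthy.

Coordinates are 0-based half-open on the template's plus strand
throughout; minus-strand sites store their plus-strand projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .homology import COIPanel, PanelError
from .seq import (
    AssayDefinition,
    IUPACSequence,
    Oligo,
    SequenceError,
    offset_mismatch_counts,
    reverse_complement,
)


@dataclass(frozen=True)
class BindingSite:
    oligo_role: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError("binding site interval must be non-empty")


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    probe_site: BindingSite | None
    length_bp: int
    valid: bool

    def __post_init__(self) -> None:
        assert self.length_bp == self.reverse_site.end - self.forward_site.start


def find_binding_sites(
    oligo: Oligo, template: IUPACSequence, max_mismatches: int = 0
) -> list[BindingSite]:
    """All ungapped placements of ``oligo`` on either strand within the
    mismatch tolerance, sorted by (start, strand).

    A '+' site means the oligo's written 5'→3' sequence matches the plus
    strand; a '-' site means it matches the minus strand (its reverse
    complement matches the plus strand). Degenerate bases on either side
    count as matches when their base sets intersect.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    tpl = template.bases
    L = len(oligo)
    if len(tpl) < L:
        raise SequenceError(
            f"template {template.id!r} shorter than oligo {oligo.name!r}"
        )
    counts = {
        "+": offset_mismatch_counts(oligo.bases.bases, tpl),
        "-": offset_mismatch_counts(reverse_complement(oligo.bases).bases, tpl),
    }
    sites = []
    for strand in "+-":
        for start in np.flatnonzero(counts[strand] <= max_mismatches):
            sites.append(
                BindingSite(
                    oligo_role=oligo.role,
                    start=int(start),
                    end=int(start) + L,
                    strand=strand,
                    mismatches=int(counts[strand][start]),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicon(
    assay: AssayDefinition,
    template: IUPACSequence,
    max_mismatches: int = 0,
    size_range: tuple[int, int] = (70, 150),
) -> list[AmpliconPrediction]:
    """All candidate amplicons of an assay on a template, sorted by length.

    The forward primer must bind the plus strand upstream of a
    minus-strand reverse-primer site, with a product length (forward
    start to reverse end) inside ``size_range``. ``valid`` requires the
    probe to bind (either strand) strictly between the primers' 3' ends,
    i.e. within ``[forward.end, reverse.start)``.
    """
    lo, hi = size_range
    fwd_sites = [
        s
        for s in find_binding_sites(assay.forward, template, max_mismatches)
        if s.strand == "+"
    ]
    rev_sites = [
        s
        for s in find_binding_sites(assay.reverse, template, max_mismatches)
        if s.strand == "-"
    ]
    if not fwd_sites or not rev_sites:
        return []
    probe_sites = find_binding_sites(assay.probe, template, max_mismatches)
    preds = []
    for f in fwd_sites:
        for r in rev_sites:
            length = r.end - f.start
            if f.start >= r.start or not lo <= length <= hi:
                continue
            inner = [
                p for p in probe_sites if p.start >= f.end and p.end <= r.start
            ]
            probe_site = inner[0] if inner else None
            preds.append(
                AmpliconPrediction(
                    template_id=template.id,
                    forward_site=f,
                    reverse_site=r,
                    probe_site=probe_site,
                    length_bp=length,
                    valid=probe_site is not None,
                )
            )
    preds.sort(key=lambda p: (p.length_bp, p.forward_site.start))
    return preds


@dataclass
class SpeciesValidation:
    species: str
    is_target: bool
    amplifies: bool  # valid amplicon at 0 mismatches
    profile_total: int  # best total mismatches over the three oligos


@dataclass
class PanelValidationReport:
    assay_species: str
    rows: list[SpeciesValidation]
    passes: bool
    failing_cons: list[str]


def validate_assay_panel(
    assay: AssayDefinition,
    panel: COIPanel,
    size_range: tuple[int, int] = (70, 150),
    consensus: bool = True,
) -> PanelValidationReport:
    """Check an assay against a whole panel at zero mismatch tolerance.

    Passes iff the assay's own target yields a valid amplicon and no CON
    or other species does. Each row also carries the best total mismatch
    profile as supporting evidence.
    """
    from .specificity import mismatch_profile

    if assay.species not in panel.target_species:
        raise PanelError(
            f"assay target {assay.species!r} not among panel targets"
        )
    rows = []
    failing = []
    target_ok = False
    for name in panel.species_names:
        rep = panel.representative(name, consensus=consensus)
        preds = predict_amplicon(assay, rep, max_mismatches=0, size_range=size_range)
        amplifies = any(p.valid for p in preds)
        total = mismatch_profile(assay, rep).total
        is_target = name == assay.species
        rows.append(
            SpeciesValidation(
                species=name, is_target=is_target, amplifies=amplifies, profile_total=total
            )
        )
        if is_target:
            target_ok = amplifies
        elif amplifies:
            failing.append(name)
    return PanelValidationReport(
        assay_species=assay.species,
        rows=rows,
        passes=target_ok and not failing,
        failing_cons=failing,
    )
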