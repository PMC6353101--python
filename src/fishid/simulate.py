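"""Synthetic data generators: COI-like panels and qPCR run exports.

Everything downstream is validated offline against data built here:

* **panels** — an ancestral COI-like sequence carries each assay's exact
  primer/probe footprints; each species derives from it by an exact
  number of substitutions placed outside footprints, plus an explicit
  per-oligo mismatch count inside the footprints for control species.
  Pairwise identities and per-oligo mismatch counts are therefore planted
  quantities that the homology and specificity modules must recover.
* **qPCR runs** — per-well Cq values are drawn from per-(sample, assay)
  means and SEMs (SEM used as the per-replicate standard deviation,
  scaled by ``noise_scale``); undetectable pairs emit "Undetermined"
  wells with a failing amplification status and sub-threshold deltaRn.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import COIPanel
from .seq import AssayDefinition, IUPACSequence, IUPAC_SETS, reverse_complement, write_fasta

_BASES = np.array(list("ACGT"))

#: deltaRn emitted for detectable wells (positive signal) and for phantom /
#: undetectable wells. Reporter magnitudes are instrument- and dye-specific
#: and are not modelled; these are invented defaults on either side of the
#: 0.3 decoder gate.
DELTA_RN_POSITIVE = 1.0
DELTA_RN_PHANTOM = 0.05

CQ_MAX_CYCLES = 40.0  # runs are 40 cycles; simulated Cq is clipped here


class FixtureError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    role: str  # 'target' or 'con'
    substitutions: int
    in_great_lakes: bool = True

    def __post_init__(self) -> None:
        if self.role not in ("target", "con"):
            raise FixtureError(f"{self.name}: role must be 'target' or 'con'")
        if self.substitutions < 0:
            raise FixtureError(f"{self.name}: negative substitution count")


@dataclass(frozen=True)
class PlantedAssay:
    """Where an assay's footprints sit on the ancestor, and which species
    carry how many mismatches inside them.

    ``mismatches`` maps species name -> (forward, reverse, probe) counts;
    the assay's own target carries (0, 0, 0) implicitly. The reverse
    primer's plus-strand footprint holds the reverse complement of its
    written sequence. Species not listed keep the ancestral (exact)
    footprints, so list every non-target that must not amplify.
    """

    assay: AssayDefinition
    fwd_start: int
    probe_offset: int | None = None  # gap between forward end and probe start
    mismatches: Mapping[str, tuple[int, int, int]] = field(default_factory=dict)

    def footprints(self) -> dict[str, tuple[int, int]]:
        a = self.assay
        lf, lr, lp = len(a.forward), len(a.reverse), len(a.probe)
        fwd = (self.fwd_start, self.fwd_start + lf)
        rev_start = self.fwd_start + a.expected_amplicon_bp - lr
        rev = (rev_start, rev_start + lr)
        gap = self.probe_offset if self.probe_offset is not None else (
            (rev_start - fwd[1] - lp) // 2
        )
        probe = (fwd[1] + gap, fwd[1] + gap + lp)
        if probe[0] < fwd[1] or probe[1] > rev[0]:
            raise FixtureError(
                f"{a.species}: probe footprint {probe} not strictly between primers"
            )
        return {"forward": fwd, "reverse": rev, "probe": probe}


@dataclass
class PanelSpec:
    seed: int
    species: list[SpeciesSpec]
    planted_assays: list[PlantedAssay] = field(default_factory=list)
    length_bp: int = 652

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise FixtureError("duplicate species names in panel spec")


@dataclass
class GeneratedPanel:
    sequences: dict[str, IUPACSequence]
    manifest: dict

    def to_panel(self, spec: PanelSpec) -> COIPanel:
        targets = {
            s.name: [self.sequences[s.name]] for s in spec.species if s.role == "target"
        }
        cons = {
            s.name: ([self.sequences[s.name]], s.in_great_lakes)
            for s in spec.species
            if s.role == "con"
        }
        return COIPanel(target_species=targets, con_species=cons)

    def write(self, fasta_path: str | Path, manifest_path: str | Path | None = None) -> None:
        write_fasta(self.sequences.values(), fasta_path)
        if manifest_path is not None:
            import json

            Path(manifest_path).write_text(json.dumps(self.manifest, indent=1, sort_keys=True))


def _mutate_positions(bases: list[str], positions: Sequence[int], rng, avoid=None) -> None:
    """Substitute each position to a base incompatible with the current one."""
    for pos in positions:
        current = bases[pos]
        choices = [b for b in "ACGT" if b not in IUPAC_SETS[current]]
        bases[pos] = choices[rng.integers(len(choices))]


def generate_panel(spec: PanelSpec) -> GeneratedPanel:
    """Build a panel of COI-like sequences with planted identities/footprints.

    The ancestor is uniform-random A/C/G/T with every planted assay's
    exact footprints written in; species then acquire exactly
    ``substitutions`` changes outside all footprints, plus the explicit
    per-oligo footprint mismatches from each :class:`PlantedAssay`.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length_bp

    # footprint layout, checked for overlap on the ancestor
    layout: list[tuple[PlantedAssay, str, tuple[int, int]]] = []
    occupied: list[tuple[int, int]] = []
    for planted in spec.planted_assays:
        for role, (start, end) in planted.footprints().items():
            if start < 0 or end > L:
                raise FixtureError(
                    f"{planted.assay.species}/{role}: footprint ({start},{end}) outside template of {L} bp"
                )
            for s0, e0 in occupied:
                if start < e0 and s0 < end:
                    raise FixtureError(
                        f"{planted.assay.species}/{role}: footprint overlaps another planted footprint"
                    )
            occupied.append((start, end))
            layout.append((planted, role, (start, end)))

    ancestor = list(rng.choice(_BASES, size=L))
    for planted, role, (start, end) in layout:
        a = planted.assay
        oligo = {"forward": a.forward, "reverse": a.reverse, "probe": a.probe}[role]
        site = oligo.bases.bases if role != "reverse" else reverse_complement(oligo.bases).bases
        ancestor[start:end] = list(site)

    footprint_mask = np.zeros(L, dtype=bool)
    for _, _, (start, end) in layout:
        footprint_mask[start:end] = True
    free_positions = np.flatnonzero(~footprint_mask)

    sequences: dict[str, IUPACSequence] = {}
    manifest: dict = {
        "seed": spec.seed,
        "length_bp": L,
        "ancestor": "".join(ancestor),
        "species": {},
        "assays": {
            p.assay.species: {role: iv for role, iv in p.footprints().items()}
            for p in spec.planted_assays
        },
    }

    for sp in spec.species:
        if sp.substitutions > len(free_positions):
            raise FixtureError(
                f"{sp.name}: {sp.substitutions} substitutions exceed the "
                f"{len(free_positions)} positions outside planted footprints"
            )
        bases = list(ancestor)
        subs = sorted(
            rng.choice(free_positions, size=sp.substitutions, replace=False).tolist()
        )
        _mutate_positions(bases, subs, rng)

        planted_counts: dict[str, dict[str, int]] = {}
        for planted in spec.planted_assays:
            per_oligo = planted.mismatches.get(sp.name)
            if per_oligo is None:
                continue
            fps = planted.footprints()
            for role, count in zip(("forward", "reverse", "probe"), per_oligo):
                start, end = fps[role]
                if count > end - start:
                    raise FixtureError(
                        f"{sp.name}: {count} mismatches exceed {role} footprint length"
                    )
                pos = sorted(
                    rng.choice(np.arange(start, end), size=count, replace=False).tolist()
                )
                _mutate_positions(bases, pos, rng)
                planted_counts.setdefault(planted.assay.species, {})[role] = count
        sequences[sp.name] = IUPACSequence(id=sp.name, bases="".join(bases))
        manifest["species"][sp.name] = {
            "role": sp.role,
            "substitutions": subs,
            "footprint_mismatches": planted_counts,
        }
    return GeneratedPanel(sequences=sequences, manifest=manifest)


def synthetic_target_template(
    assay: AssayDefinition, seed: int = 0, length_bp: int = 652, fwd_start: int = 120
) -> IUPACSequence:
    """A synthetic barcode-like template carrying one assay's exact
    footprints (a stand-in for a reference barcode record of the assay's
    target species). The predicted amplicon has the assay's expected size.
    """
    spec = PanelSpec(
        seed=seed,
        length_bp=length_bp,
        species=[SpeciesSpec(name=assay.species, role="target", substitutions=0)],
        planted_assays=[PlantedAssay(assay=assay, fwd_start=fwd_start)],
    )
    seq = generate_panel(spec).sequences[assay.species]
    return IUPACSequence(
        id=assay.species.replace(" ", "_"),
        bases=seq.bases,
        description="synthetic barcode-like template with planted assay footprints",
    )


# ---------------------------------------------------------------------------
# qPCR run simulation


@dataclass(frozen=True)
class CqStat:
    """Per-(sample species, assay) Cq statistics; mean None = undetectable."""

    mean_cq: float | None
    sem: float = 0.0
    delta_rn_mean: float = DELTA_RN_POSITIVE

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise FixtureError("sem must be >= 0")


@dataclass
class RunSpec:
    """Design of a simulated qPCR run.

    ``design`` rows are (sample_id, true_species, n_replicates); each
    sample is assayed against every assay named for it in ``assays_for``
    (one probe set's worth in a multiplexed plate). ``stats`` must cover
    every (true_species, assay_species) pair that will be emitted.
    """

    seed: int
    design: list[tuple[str, str, int]]
    assays_for: dict[str, list[str]]  # sample_id -> assay species list
    stats: Mapping[tuple[str, str], CqStat]
    noise_scale: float = 1.0
    dyes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise FixtureError("noise_scale must be >= 0")
        for sample_id, species, n_rep in self.design:
            if n_rep < 1:
                raise FixtureError(f"{sample_id}: n_replicates must be >= 1")
            for assay in self.assays_for[sample_id]:
                if (species, assay) not in self.stats:
                    raise FixtureError(
                        f"missing Cq stats for sample species {species!r} vs assay {assay!r}"
                    )


@dataclass
class GeneratedRun:
    wells: pd.DataFrame
    truth: dict[str, str]

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)

    def write_truth(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"sample": s, "species": sp} for s, sp in sorted(self.truth.items())]
        ).to_csv(path, sep="\t", index=False)


def _well_names(n: int):
    for i in range(n):
        yield f"{'ABCDEFGH'[(i // 12) % 8]}{i % 12 + 1}"


def generate_qpcr_run(spec: RunSpec) -> GeneratedRun:
    """Simulate a qPCR export (QuantStudio-like CSV columns) plus truth table.

    Detectable pairs draw ``Cq ~ Normal(mean, noise_scale * sem)`` clipped
    to (0, 40] cycles, with true amplification status and the positive
    deltaRn; undetectable pairs emit "Undetermined" with a failing status
    and phantom-level deltaRn.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: dict[str, str] = {}
    n_wells = sum(n * len(spec.assays_for[s]) for s, _, n in spec.design)
    names = _well_names(n_wells)
    for sample_id, species, n_rep in spec.design:
        truth[sample_id] = species
        for assay in spec.assays_for[sample_id]:
            stat = spec.stats[(species, assay)]
            for _ in range(n_rep):
                well = next(names)
                if stat.mean_cq is None:
                    cq_text, status, drn = "Undetermined", "No Amp", DELTA_RN_PHANTOM
                else:
                    cq = rng.normal(stat.mean_cq, spec.noise_scale * stat.sem)
                    cq = float(np.clip(cq, 0.01, CQ_MAX_CYCLES))
                    cq_text, status, drn = f"{cq:.4f}", "Amp", stat.delta_rn_mean
                rows.append(
                    {
                        "Well": well,
                        "Sample": sample_id,
                        "Target": assay,
                        "Dye": spec.dyes.get(assay, ""),
                        "Cq": cq_text,
                        "Amp Status": status,
                        "Delta Rn": drn,
                    }
                )
    return GeneratedRun(wells=pd.DataFrame(rows), truth=truth)
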