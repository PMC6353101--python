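"""Loaders for the packaged reference tables.

The package ships, as plain TSV under ``fishid/data``:

* the eight validated assays (oligos, dyes, concentrations, amplicon sizes),
* per-(assay, sample-species) Cq statistics from the single-plex
  validation runs and from the mixed-template multiplex runs,
* the blinded-trial sample design (which species groups, how many samples,
  which probe set),
* the target/CON homology table (base-pair matches and integer percents),
* itemized cost components, printed cost totals, and step-wise time
  estimates for the three identification methods.

These are inputs to the pipeline — measured or published quantities the
software consumes — not outputs it claims to compute.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .cost import CostComponent, MethodCostTable, TimeEstimate
from .seq import AssayDefinition, IUPACSequence, Oligo
from .simulate import CqStat, RunSpec


def _data_path(name: str) -> Path:
    return Path(resources.files("fishid").joinpath("data", name))


def _read_tsv(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t", dtype=str, keep_default_na=False)


def load_assays() -> dict[str, AssayDefinition]:
    """The eight validated species assays, keyed by target species."""
    out: dict[str, AssayDefinition] = {}
    for _, row in _read_tsv("assays.tsv").iterrows():
        sp = row["species"]

        def oligo(role: str, column: str) -> Oligo:
            return Oligo(
                name=f"{sp} {role}",
                role=role,
                bases=IUPACSequence(id=f"{sp}:{role}", bases=row[column]),
            )

        out[sp] = AssayDefinition(
            species=sp,
            forward=oligo("forward", "forward"),
            reverse=oligo("reverse", "reverse"),
            probe=oligo("probe", "probe"),
            dye=row["dye"],
            forward_conc_nM=float(row["forward_conc_nM"]),
            reverse_conc_nM=float(row["reverse_conc_nM"]),
            probe_conc_nM=float(row["probe_conc_nM"]),
            annealing_temp_C=float(row["annealing_temp_C"]),
            expected_amplicon_bp=int(row["expected_amplicon_bp"]),
        )
    return out


def probe_sets() -> dict[int, list[str]]:
    """Probe-set grouping: set number -> the four multiplexed assay species."""
    df = _read_tsv("assays.tsv")
    return {
        int(ps): grp["species"].tolist()
        for ps, grp in df.groupby("probe_set", sort=True)
    }


def assay_dyes() -> dict[str, str]:
    df = _read_tsv("assays.tsv")
    return dict(zip(df["species"], df["dye"]))


def load_cq_stats(which: str = "singleplex") -> dict[tuple[str, str], CqStat]:
    """Cq statistics keyed (sample_species, assay_species).

    ``which`` selects the single-plex validation table or the
    mixed-template multiplex table. Blank means = undetectable.
    """
    if which not in ("singleplex", "multiplex"):
        raise ValueError("which must be 'singleplex' or 'multiplex'")
    df = _read_tsv(f"cq_stats_{which}.tsv")
    stats: dict[tuple[str, str], CqStat] = {}
    for _, row in df.iterrows():
        mean = row.get("mean_cq", "")
        sem = row.get("sem", "")
        stats[(row["sample_species"], row["assay_species"])] = CqStat(
            mean_cq=float(mean) if str(mean).strip() else None,
            sem=float(sem) if str(sem).strip() else 0.0,
        )
    return stats


def load_blinded_design() -> pd.DataFrame:
    """Blinded-trial sample groups: probe_set, species, n_samples, role."""
    df = _read_tsv("blinded_design.tsv")
    df["probe_set"] = df["probe_set"].astype(int)
    df["n_samples"] = df["n_samples"].astype(int)
    return df


def load_homology_table() -> pd.DataFrame:
    """Published target-vs-CON homology rows (values as printed)."""
    df = _read_tsv("homology_panel.tsv")
    for col in ("matches", "compared", "percent"):
        df[col] = df[col].astype(int)
    df["in_great_lakes"] = df["in_great_lakes"].eq("Y")
    df["negative_control"] = df["negative_control"].eq("Y")
    return df


def blinded_run_spec(seed: int, noise_scale: float = 1.0) -> RunSpec:
    """The full blinded-trial design as a simulation spec.

    Every sample group in the design becomes that many individual samples,
    each assayed in duplicate against the four assays of its probe set.
    (Sample species, assay) pairs absent from the single-plex Cq table are
    filled in as undetectable — those are the "-" cells and the
    CON groups never tested against a given assay.
    """
    design_df = load_blinded_design()
    sets = probe_sets()
    stats = dict(load_cq_stats("singleplex"))

    design: list[tuple[str, str, int]] = []
    assays_for: dict[str, list[str]] = {}
    counter = 0
    for _, row in design_df.iterrows():
        assay_list = sets[row["probe_set"]]
        for _ in range(row["n_samples"]):
            counter += 1
            sample_id = f"blind-{counter:03d}"
            design.append((sample_id, row["species"], 2))
            assays_for[sample_id] = assay_list
            for assay in assay_list:
                stats.setdefault((row["species"], assay), CqStat(mean_cq=None))
    return RunSpec(
        seed=seed,
        design=design,
        assays_for=assays_for,
        stats=stats,
        noise_scale=noise_scale,
        dyes=assay_dyes(),
    )


def blinded_truth_roles() -> dict[str, str]:
    """Species -> role ('target' or 'control') for the blinded design."""
    df = load_blinded_design()
    return dict(zip(df["species"], df["role"]))


#: per-oligo (forward, reverse, probe) footprint mismatches planted for each
#: assay's control species in the validation panel. Totals follow the
#: in-silico specificity findings: the closest whitefish/sculpin relatives
#: differ by only 1-2 bases (concentrated on reverse primer and probe),
#: the Great Lakes whitefish CONs by 3-5, largemouth bass by 5, and
#: everything else by 6 or more.
VALIDATION_CON_MISMATCHES: dict[str, dict[str, tuple[int, int, int]]] = {
    "Lake Whitefish": {
        "Cisco": (1, 1, 1),
        "Bloater": (1, 1, 2),
        "Kiyi": (1, 2, 2),
        "Broad Whitefish": (0, 1, 0),
        "Sardine Cisco": (0, 1, 1),
    },
    "Smallmouth Bass": {"Largemouth Bass": (1, 2, 2)},
    "Deepwater Sculpin": {"Fourhorn Sculpin": (0, 0, 1)},
    "Spottail Shiner": {"Pugnose Shiner": (2, 2, 2), "Blackchin Shiner": (2, 3, 2)},
    "Rainbow Smelt": {"Pacific Rainbow Smelt": (2, 2, 2)},
    "Yellow Perch": {"Channel Darter": (3, 2, 2), "Blackside Darter": (2, 2, 3)},
    "Round Whitefish": {"Pygmy Whitefish": (2, 2, 2)},
    "Brook Trout": {"Bull Trout": (2, 2, 2), "Lake Trout": (2, 2, 3)},
}

#: default mismatches planted for species unrelated to an assay (non-target,
#: different genus): inside the 10-19 total range seen across panels.
_NON_TARGET_MISMATCHES = (5, 5, 5)


def validation_panel_spec(seed: int, length_bp: int = 1600, substitutions: int = 60):
    """A full in-silico validation panel: all eight assays planted.

    The synthetic reference region is longer than one barcode so the
    eight assays' footprints fit side by side without overlap. Every
    species that is not an assay's target carries planted mismatches
    inside that assay's footprints — its CONs per
    :data:`VALIDATION_CON_MISMATCHES`, everything else at non-target
    levels — so no assay can amplify anything but its own target at zero
    mismatch tolerance.
    """
    from .simulate import PanelSpec, PlantedAssay, SpeciesSpec

    assays = load_assays()
    hom = load_homology_table()
    targets = list(assays)
    cons = sorted({c for m in VALIDATION_CON_MISMATCHES.values() for c in m})
    gl = dict(zip(hom["con_species"], hom["in_great_lakes"]))

    species = [SpeciesSpec(name=t, role="target", substitutions=substitutions) for t in targets]
    species += [
        SpeciesSpec(name=c, role="con", substitutions=substitutions, in_great_lakes=bool(gl.get(c, True)))
        for c in cons
    ]

    planted = []
    block = length_bp // len(targets)
    for i, target in enumerate(targets):
        assay = assays[target]
        mismatches = dict(VALIDATION_CON_MISMATCHES[target])
        for sp in species:
            if sp.name == target or sp.name in mismatches:
                continue
            mismatches[sp.name] = _NON_TARGET_MISMATCHES
        planted.append(
            PlantedAssay(assay=assay, fwd_start=i * block + 10, mismatches=mismatches)
        )
    return PanelSpec(seed=seed, species=species, planted_assays=planted, length_bp=length_bp)


def load_cost_tables() -> dict[str, MethodCostTable]:
    """Itemized cost tables per method, with the printed totals attached."""
    comps = _read_tsv("cost_components.tsv")
    totals = _read_tsv("cost_totals.tsv").set_index("method")
    out: dict[str, MethodCostTable] = {}
    for method, grp in comps.groupby("method", sort=False):
        components = [
            CostComponent(
                label=row["label"],
                per_sample_cost=float(row["per_sample"]),
                per_batch_cost=float(row["per_batch"]) if row["per_batch"].strip() else None,
            )
            for _, row in grp.iterrows()
        ]
        printed = totals.loc[method]
        out[method] = MethodCostTable(
            method_name=method,
            components=components,
            printed_per_sample_total=float(printed["printed_per_sample"]),
            printed_per_batch_total=float(printed["printed_per_batch"]),
        )
    return out


def load_time_estimates() -> dict[str, TimeEstimate]:
    """Step-wise turnaround-time estimates per method (hours)."""
    df = _read_tsv("time_steps.tsv")
    out: dict[str, TimeEstimate] = {}
    for method, grp in df.groupby("method", sort=False):
        out[method] = TimeEstimate(
            method_name=method,
            steps=[
                (row["step"], float(row["min_hours"]), float(row["max_hours"]))
                for _, row in grp.iterrows()
            ],
        )
    return out
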