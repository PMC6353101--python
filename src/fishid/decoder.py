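"""Automated species decoder for probe-based qPCR exports.

A well is a positive amplification only when three gates all pass:

* quantification cycle ``Cq <= cq_cutoff`` (default 25 cycles — target
  species at the standardized 100 ng DNA input all amplify below this,
  while cross-reactions sit well above it),
* the instrument's amplification-status verdict is true (rejects phantom
  signals with spurious Cq values),
* normalized reporter ``dRn >= delta_rn_min`` (default 0.3 — signal
  magnitude over dye background).

Replicate wells are aggregated per assay, and a sample is called as the
species whose assay is positive; zero positives is NONE, two or more is
MULTIPLE (mixed DNA). Blinded runs are scored as identification accuracy
over target-species samples plus a false-positive count over control and
non-target samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

NONE_CALL = "NONE"
MULTIPLE_CALL = "MULTIPLE"


class QPCRParseError(ValueError):
    """Raised for malformed qPCR export files."""


@dataclass(frozen=True)
class QPCRWellRecord:
    """One well of a qPCR export.

    ``cq`` is None when the instrument reported "Undetermined".
    ``dna_input_ng`` is carried as metadata only (reactions are
    standardized at 100 ng); it plays no part in the decoding rules.
    """

    well: str
    sample_id: str
    target_species: str
    dye: str
    cq: float | None
    amp_status: bool
    delta_rn: float | None
    dna_input_ng: float = 100.0

    def __post_init__(self) -> None:
        if self.cq is not None and not 0 < self.cq <= 40:
            raise ValueError(f"well {self.well}: Cq {self.cq} outside (0, 40]")
        if self.delta_rn is not None and self.delta_rn < 0:
            raise ValueError(f"well {self.well}: negative deltaRn")


@dataclass
class DecoderConfig:
    """Decoder thresholds; defaults are the validated single-species values.

    ``mixed_sample_mode`` marks a run as mixed-template: the Cq gate is
    then taken from ``mixed_cq_cutoff`` (mixed-DNA reactions shift some
    assays' Cq above 25, so the cutoff is exposed as a parameter rather
    than fixed).
    """

    cq_cutoff: float = 25.0
    delta_rn_min: float = 0.3
    require_amp_status: bool = True
    replicate_rule: str = "mean"  # mean | all | any
    mixed_sample_mode: bool = False
    mixed_cq_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.cq_cutoff < 40:
            raise ValueError("cq_cutoff must lie in (0, 40)")
        if self.delta_rn_min < 0:
            raise ValueError("delta_rn_min must be >= 0")
        if self.replicate_rule not in ("mean", "all", "any"):
            raise ValueError("replicate_rule must be one of mean/all/any")

    @property
    def effective_cq_cutoff(self) -> float:
        return self.mixed_cq_cutoff if self.mixed_sample_mode else self.cq_cutoff


@dataclass
class SpeciesCall:
    """Per-sample verdict: per-assay calls plus the identified species."""

    sample_id: str
    calls: list[tuple[str, float | None, bool]]  # (species, mean_cq, positive)
    identified_species: str  # species name, NONE_CALL, or MULTIPLE_CALL

    @property
    def positive_species(self) -> list[str]:
        return [sp for sp, _, pos in self.calls if pos]


#: default column map: canonical field -> lower-cased header names accepted
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "well": ("well", "well position"),
    "sample_id": ("sample", "sample name", "sample id"),
    "target_species": ("target", "target name"),
    "dye": ("dye", "reporter"),
    "cq": ("cq", "ct", "crt"),
    "amp_status": ("amp status", "amplification status", "amp_status"),
    "delta_rn": ("delta rn", "deltarn", "delta_rn", "drn"),
}

_TRUE_TOKENS = {"amp", "true", "y", "yes", "1"}
_FALSE_TOKENS = {"no amp", "false", "n", "no", "0", ""}


def _parse_cq(value) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in ("undetermined", "undeterm", "nan", "-"):
        return None
    return float(text)


def _parse_status(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS or text == "nan":
        return False
    raise QPCRParseError(f"unrecognized amplification status {value!r}")


def parse_qpcr_export(
    path: str | Path, column_map: Mapping[str, Sequence[str]] | None = None
) -> list[QPCRWellRecord]:
    """Parse an instrument-style CSV export into well records.

    Header matching is case-insensitive with a configurable column map.
    "Undetermined" or empty Cq parses as missing (never 0). The dye column
    is optional; all gate columns are mandatory.
    """
    cmap = {k: tuple(v) for k, v in (column_map or DEFAULT_COLUMNS).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lower_cols = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for fieldname, aliases in cmap.items():
        for alias in aliases:
            if alias in lower_cols:
                resolved[fieldname] = lower_cols[alias]
                break
    mandatory = ("well", "sample_id", "target_species", "cq", "amp_status", "delta_rn")
    missing = [m for m in mandatory if m not in resolved]
    if missing:
        raise QPCRParseError(
            f"{path}: missing mandatory columns {missing}; columns found: {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        drn_text = str(row[resolved["delta_rn"]]).strip()
        records.append(
            QPCRWellRecord(
                well=row[resolved["well"]],
                sample_id=row[resolved["sample_id"]],
                target_species=row[resolved["target_species"]],
                dye=row[resolved["dye"]] if "dye" in resolved else "",
                cq=_parse_cq(row[resolved["cq"]]),
                amp_status=_parse_status(row[resolved["amp_status"]]),
                delta_rn=float(drn_text) if drn_text not in ("", "nan") else None,
            )
        )
    return records


def call_well(record: QPCRWellRecord, config: DecoderConfig | None = None) -> bool:
    """True iff the well passes all three gates (Cq, status, deltaRn)."""
    config = config or DecoderConfig()
    if record.cq is None or record.cq > config.effective_cq_cutoff:
        return False
    if config.require_amp_status and not record.amp_status:
        return False
    if record.delta_rn is None or record.delta_rn < config.delta_rn_min:
        return False
    return True


def decode_sample(
    records: Sequence[QPCRWellRecord], config: DecoderConfig | None = None
) -> SpeciesCall:
    """Aggregate one sample's replicate wells into a species call.

    Wells are grouped by assay (target species). Under the default
    ``mean`` rule, wells passing the status and deltaRn gates contribute
    their Cq to a mean which is then thresholded; ``all``/``any`` combine
    per-well calls conjunctively/disjunctively. The sample is identified
    as the single positive assay's species, NONE when nothing is
    positive, MULTIPLE when several are.
    """
    config = config or DecoderConfig()
    if not records:
        raise ValueError("decode_sample requires at least one well record")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")

    by_assay: dict[str, list[QPCRWellRecord]] = {}
    for rec in records:
        by_assay.setdefault(rec.target_species, []).append(rec)

    calls = []
    for species in sorted(by_assay):
        wells = by_assay[species]
        if config.replicate_rule == "mean":
            passing = [
                w.cq
                for w in wells
                if w.cq is not None
                and (w.amp_status or not config.require_amp_status)
                and (w.delta_rn is not None and w.delta_rn >= config.delta_rn_min)
            ]
            mean_cq = sum(passing) / len(passing) if passing else None
            positive = mean_cq is not None and mean_cq <= config.effective_cq_cutoff
        else:
            verdicts = [call_well(w, config) for w in wells]
            positive = all(verdicts) if config.replicate_rule == "all" else any(verdicts)
            passing = [w.cq for w in wells if call_well(w, config)]
            mean_cq = sum(passing) / len(passing) if passing else None
        calls.append((species, mean_cq, positive))

    positives = [sp for sp, _, pos in calls if pos]
    if not positives:
        identified = NONE_CALL
    elif len(positives) == 1:
        identified = positives[0]
    else:
        identified = MULTIPLE_CALL
    return SpeciesCall(
        sample_id=next(iter(sample_ids)), calls=calls, identified_species=identified
    )


def decode_run(
    records: Sequence[QPCRWellRecord], config: DecoderConfig | None = None
) -> list[SpeciesCall]:
    """Decode every sample present in a run (samples sorted by id)."""
    by_sample: dict[str, list[QPCRWellRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    return [decode_sample(by_sample[s], config) for s in sorted(by_sample)]


@dataclass
class BlindedMetrics:
    """Scoring of a blinded run against ground truth."""

    n_target_samples: int
    n_correct: int
    accuracy_percent: float | None  # None when no target samples
    n_nontarget_samples: int
    false_positive_count: int
    confusion: pd.DataFrame = field(repr=False, default=None)


def evaluate_blinded(
    calls: Sequence[SpeciesCall],
    truth: Mapping[str, str | None],
    target_species: Iterable[str] | None = None,
) -> BlindedMetrics:
    """Score decoded calls against known sample identities.

    ``truth`` maps sample id to its true species (or None for a blank).
    A sample counts toward accuracy when its truth is a panel target
    species (by default, any species that has an assay among the calls);
    samples whose truth is a CON/non-target count toward the
    false-positive tally when the decoder names any species for them.
    """
    missing = [c.sample_id for c in calls if c.sample_id not in truth]
    if missing:
        raise ValueError(f"samples missing from truth table: {missing[:5]}")
    if target_species is None:
        target_species = {sp for c in calls for sp, _, _ in c.calls}
    targets = set(target_species)

    n_target = n_correct = n_nontarget = n_fp = 0
    rows = []
    for call in calls:
        true_sp = truth[call.sample_id]
        if true_sp in targets:
            n_target += 1
            correct = call.identified_species == true_sp
            n_correct += int(correct)
        else:
            n_nontarget += 1
            if call.identified_species not in (NONE_CALL,):
                n_fp += 1
        for sp, _, pos in call.calls:
            rows.append(
                {"true_species": true_sp or "blank", "assay": sp, "positive": int(pos)}
            )
    confusion = (
        pd.DataFrame(rows)
        .groupby(["true_species", "assay"], as_index=False)
        .agg(n_samples=("positive", "size"), n_positive=("positive", "sum"))
    )
    accuracy = 100.0 * n_correct / n_target if n_target else None
    return BlindedMetrics(
        n_target_samples=n_target,
        n_correct=n_correct,
        accuracy_percent=accuracy,
        n_nontarget_samples=n_nontarget,
        false_positive_count=n_fp,
        confusion=confusion,
    )
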