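"""Peak-area to mole-fraction conversion.

Electrospray ionization efficiency differs strongly between lipid classes,
so integrated parent-ion peak areas are corrected by an analytical response
factor (RF, the slope of peak intensity vs. injected mass of a calibration
standard) and by the parent-ion monoisotopic mass before normalizing:

    x_i = (I_i / (RF_i * mi_i)) / sum_j (I_j / (RF_j * mi_j))

RF standards are assigned per (headgroup, backbone) combination: headgroups
dominate ionization differences, so each combination maps to the standard
with the most similar headgroup (all tetraethers share the glycosyl-GDGT
standard; all aminolipids share the DGTS-d9 standard).  Absent a calibration
file, every standard's slope defaults to 1.0 — mass-normalized peak-area
fractions — since the slopes are instrument-specific, lab-supplied numbers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import monoisotopic_mass
from .lipids import LipidSpec, assemble, parse_ipl_name

__all__ = [
    "RfTable",
    "IplRecord",
    "UnassignedResponseFactor",
    "assign_response_factor",
    "build_records",
    "mole_fractions",
    "quantify_dataset",
    "read_abundance_csv",
    "records_from_frame",
]

STANDARD_IDS = tuple(range(1, 14))

DEFAULT_ADDUCT = "proton"


class UnassignedResponseFactor(KeyError):
    """No calibration standard is assigned to this headgroup/backbone pair."""


def _load_assignments() -> dict[tuple[str, str], int]:
    path = resources.files("lipidzc.data").joinpath("rf_assignments.csv")
    with path.open() as fh:
        return {
            (r["headgroup"], r["backbone"]): int(r["standard"])
            for r in csv.DictReader(fh)
        }


@dataclass(frozen=True)
class RfTable:
    """Map (headgroup, backbone) combinations to standards and slopes."""

    assignments: Mapping[tuple[str, str], int]
    values: Mapping[int, float]

    @classmethod
    def default(cls, values: Mapping[int, float] | None = None) -> "RfTable":
        vals = {sid: 1.0 for sid in STANDARD_IDS}
        if values:
            vals.update({int(k): float(v) for k, v in values.items()})
        if any(v <= 0 for v in vals.values()):
            raise ValueError("response-factor slopes must be positive")
        return cls(assignments=_load_assignments(), values=vals)

    def standard_for(self, spec: LipidSpec) -> int:
        if spec.is_gdgt:
            # every tetraether shares the glycosyl-GDGT standard
            return self.assignments[("H", "GDGT")]
        key = spec.rf_key
        try:
            return self.assignments[key]
        except KeyError:
            raise UnassignedResponseFactor(
                f"no response-factor standard assigned to {key}"
            ) from None

    def rf_for(self, spec: LipidSpec) -> tuple[float, int]:
        sid = self.standard_for(spec)
        return self.values[sid], sid


def assign_response_factor(spec: LipidSpec, rft: RfTable) -> tuple[float, int]:
    """Return (RF slope, standard id) for a lipid; error if unassigned."""
    return rft.rf_for(spec)


@dataclass(frozen=True)
class IplRecord:
    """One lipid in one sample, carried through the whole pipeline."""

    sample_id: str
    spec: LipidSpec
    intensity: float
    rf: float
    rf_standard: int
    mi: float
    adduct: str = DEFAULT_ADDUCT
    x: float | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak area must be >= 0")
        if self.rf <= 0 or self.mi <= 0:
            raise ValueError("RF and monoisotopic mass must be positive")


def build_records(
    rows: Iterable[tuple[str, str, float]] | pd.DataFrame,
    rft: RfTable | None = None,
    adduct: str = DEFAULT_ADDUCT,
    include_adduct_mass: bool = True,
    skip_bad: bool = False,
) -> list[IplRecord]:
    """Turn (sample_id, lipid_name, peak_area) rows into records.

    ``include_adduct_mass`` controls whether mi is the adduct-bearing parent
    ion (default) or the neutral molecule.  Unparseable annotations raise
    with the offending row number unless ``skip_bad``.
    """
    rft = rft or RfTable.default()
    if isinstance(rows, pd.DataFrame):
        it = (
            (r.sample_id, r.lipid_name, r.peak_area,
             getattr(r, "adduct", None))
            for r in rows.itertuples(index=False)
        )
    else:
        it = ((s, n, a, None) for s, n, a in rows)
    out: list[IplRecord] = []
    for i, (sample_id, lipid_name, area, row_adduct) in enumerate(it, start=1):
        try:
            spec = parse_ipl_name(str(lipid_name))
            rf, sid = rft.rf_for(spec)
            add = str(row_adduct) if row_adduct not in (None, "") else adduct
            full = assemble(spec).full
            mi = monoisotopic_mass(full, add if include_adduct_mass else "none")
            out.append(
                IplRecord(str(sample_id), spec, float(area), rf, sid, mi, add)
            )
        except (ValueError, UnassignedResponseFactor) as err:
            if skip_bad:
                continue
            raise ValueError(f"row {i}: {err}") from err
    return out


def records_from_frame(df: pd.DataFrame, **kw) -> list[IplRecord]:
    """Alias of :func:`build_records` for DataFrame input."""
    return build_records(df, **kw)


def mole_fractions(records: Sequence[IplRecord]) -> list[IplRecord]:
    """Apply the mole-fraction normalization to one sample's records.

    Records with zero peak area get x = 0 and stay in the output (so that
    bootstrap perturbation cannot resurrect them).  All-zero intensity is an
    error: the mole fractions would be undefined.
    """
    if not records:
        raise ValueError("no records to quantify")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(
            f"mole_fractions expects one sample, got {sorted(sample_ids)}"
        )
    weights = [r.intensity / (r.rf * r.mi) for r in records]
    total = sum(weights)
    if total <= 0:
        raise ValueError("all peak areas are zero; mole fractions undefined")
    return [replace(r, x=w / total) for r, w in zip(records, weights)]


def quantify_dataset(records: Sequence[IplRecord]) -> dict[str, list[IplRecord]]:
    """Group records by sample and normalize each sample to sum(x) = 1."""
    by_sample: dict[str, list[IplRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    return {sid: mole_fractions(recs) for sid, recs in by_sample.items()}


def read_abundance_csv(path) -> pd.DataFrame:
    """Read a per-sample abundance table (sample_id, lipid_name, peak_area)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "lipid_name": str})
    required = {"sample_id", "lipid_name", "peak_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns {sorted(missing)}")
    return df
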