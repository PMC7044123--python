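"""Monte-Carlo bootstrap sensitivity of sample Z_C to analytical error.

Two error sources are simulated, mirroring how the quantification could go
wrong in practice:

* manual peak-area integration: each intensity is multiplied by an
  independent draw from Uniform[1-w, 1+w] (default w = 0.30, i.e. up to
  30% of the original value);
* response-factor assignment: the RF of each (headgroup, backbone)
  combination is multiplied by 10**Uniform[-r, +r] (default r = 2, up to
  two orders of magnitude high or low), shared by every lipid carrying that
  combination.  By default the factor is also shared across samples within
  an iteration (a systematic-error model); per-sample scope is available.

Mole fractions and all weighted properties are recomputed from scratch each
iteration (999 by default), and the per-sample, per-component Z_C
distributions are summarized by their mean and standard deviation.  The
bounded-uniform shapes are the minimal reading of "vary randomly by up to";
both are isolated behind `BootstrapConfig` should other shapes be wanted.

A master seed spawns one child stream per iteration, so any iteration is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import COMPONENTS, summarize_sample
from .quantify import IplRecord, mole_fractions

__all__ = ["BootstrapConfig", "BootstrapResult", "perturb_dataset", "bootstrap_zc"]


@dataclass(frozen=True)
class BootstrapConfig:
    n_iter: int = 999
    intensity_rel_halfwidth: float = 0.30
    rf_log10_halfwidth: float = 2.0
    seed: int | None = None
    rf_perturbation_scope: str = "global"   # or "per-sample"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.intensity_rel_halfwidth < 0 or self.rf_log10_halfwidth < 0:
            raise ValueError("perturbation halfwidths must be >= 0")
        if self.rf_perturbation_scope not in ("global", "per-sample"):
            raise ValueError("scope must be 'global' or 'per-sample'")


def _rf_combos(dataset: dict[str, Sequence[IplRecord]]) -> list[tuple[str, str]]:
    combos = {r.spec.rf_key for recs in dataset.values() for r in recs}
    return sorted(combos)


def perturb_dataset(
    dataset: dict[str, Sequence[IplRecord]],
    cfg: BootstrapConfig,
    rng: np.random.Generator,
) -> dict[str, list[IplRecord]]:
    """One perturbed copy of the dataset, mole fractions recomputed."""
    w, r10 = cfg.intensity_rel_halfwidth, cfg.rf_log10_halfwidth
    combos = _rf_combos(dataset)
    if cfg.rf_perturbation_scope == "global":
        factors = {k: 10.0 ** rng.uniform(-r10, r10) for k in combos}
    out: dict[str, list[IplRecord]] = {}
    for sid in sorted(dataset):
        recs = dataset[sid]
        if cfg.rf_perturbation_scope == "per-sample":
            factors = {k: 10.0 ** rng.uniform(-r10, r10) for k in combos}
        perturbed = [
            replace(
                rec,
                intensity=rec.intensity * rng.uniform(1.0 - w, 1.0 + w),
                rf=rec.rf * factors[rec.spec.rf_key],
                x=None,
            )
            for rec in recs
        ]
        out[sid] = mole_fractions(perturbed)
    return out


@dataclass
class BootstrapResult:
    """Per-sample, per-component Z_C draws with summary statistics."""

    n_iter: int
    samples: list[str]
    zc_values: dict[tuple[str, str], np.ndarray]  # (sample, component) -> draws
    config: BootstrapConfig

    def values(self, sample: str, component: str) -> np.ndarray:
        return self.zc_values[(sample, component)]

    def mean(self, sample: str, component: str) -> float:
        return float(np.mean(self.values(sample, component)))

    def sd(self, sample: str, component: str) -> float:
        return float(np.std(self.values(sample, component), ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per iteration x sample x component."""
        rows = []
        for (sid, comp), vals in self.zc_values.items():
            for it, v in enumerate(vals):
                rows.append(
                    {"iteration": it, "sample_id": sid,
                     "component": comp, "zc": v}
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": sid,
                "component": comp,
                "zc_mean": self.mean(sid, comp),
                "zc_sd": (
                    self.sd(sid, comp) if self.n_iter > 1 else 0.0
                ),
            }
            for (sid, comp) in self.zc_values
        ]
        return pd.DataFrame(rows)


def bootstrap_zc(
    dataset: dict[str, Sequence[IplRecord]],
    cfg: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Run the full bootstrap: perturb, requantify, resummarize, collect."""
    cfg = cfg or BootstrapConfig()
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_iter)
    samples = sorted(dataset)
    store: dict[tuple[str, str], list[float]] = {
        (sid, comp): [] for sid in samples for comp in COMPONENTS
    }
    for child in children:
        rng = np.random.default_rng(child)
        perturbed = perturb_dataset(dataset, cfg, rng)
        for sid in samples:
            summ = summarize_sample(perturbed[sid])
            store[(sid, "ipl")].append(float(summ.zc_ipl))
            store[(sid, "headgroup")].append(
                np.nan if summ.zc_headgroup is None else float(summ.zc_headgroup)
            )
            store[(sid, "backbone")].append(float(summ.zc_backbone))
            store[(sid, "chain")].append(float(summ.zc_chain))
    return BootstrapResult(
        n_iter=cfg.n_iter,
        samples=samples,
        zc_values={k: np.asarray(v) for k, v in store.items()},
        config=cfg,
    )
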