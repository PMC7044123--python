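"""Abundance-weighted structural properties and average formulae per sample.

Every sample-level quantity is a ratio of abundance-weighted sums,

    Xi = sum_i Xi_ipl,i * x_i  /  sum_i n_component,i * x_i

where Xi_ipl,i is the property totalled over all components of one type in
lipid i (e.g. 32 chain carbons in a C32 diacyl lipid) and n_component,i is
how many of that component the lipid carries (2 chains for a DAG, 4
half-chains for a GDGT, ...).  Average chemical formulae come from the same
ratio with elemental abundances (and charge) as the property; full-IPL
averages use a denominator of one per lipid.

Component Z_C is then Z_C *of the average formula* — a ratio of averages —
never the abundance-weighted mean of per-lipid Z_C values; the two differ
whenever carbon counts differ between lipids.  The naive mean is exposed
separately as a diagnostic (``zc_ipl_molar_mean``).

Ring content of tetraethers is a per-GDGT property: mole fractions are
renormalized within GDGTs and each GDGT counts once, so a sample with no
GDGTs reports "undefined" (None), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chem import ChemicalFormula, zc
from .quantify import IplRecord
from .lipids import assemble

__all__ = [
    "SampleSummary",
    "weighted_property",
    "weighted_formula",
    "rings_per_gdgt",
    "summarize_sample",
    "summarize_dataset",
]

COMPONENTS = ("ipl", "headgroup", "backbone", "chain")


def weighted_property(totals, counts, x) -> float:
    """Generic abundance-weighted ratio sum(total*x)/sum(count*x)."""
    num = sum(t * xi for t, xi in zip(totals, x))
    den = sum(c * xi for c, xi in zip(counts, x))
    if den == 0:
        raise ZeroDivisionError("weighted property has zero denominator")
    return num / den


def weighted_formula(formulas, counts, x) -> ChemicalFormula:
    """Average formula per component instance (fractional counts)."""
    num = ChemicalFormula()
    den = 0.0
    for f, c, xi in zip(formulas, counts, x):
        num = num + f * float(xi)
        den += c * xi
    if den == 0:
        raise ZeroDivisionError("weighted formula has zero denominator")
    return num * (1.0 / den)


def rings_per_gdgt(records: Sequence[IplRecord]) -> float | None:
    """Abundance-weighted internal rings per GDGT; None without GDGTs."""
    gdgts = [r for r in records if r.spec.is_gdgt]
    total_x = sum(r.x for r in gdgts)
    if not gdgts or total_x == 0:
        return None
    return sum(r.spec.rings_total * r.x for r in gdgts) / total_x


@dataclass
class SampleSummary:
    """Weighted properties, average formulae and Z_C for one sample."""

    sample_id: str
    n_c: float                       # aliphatic carbons per chain
    n_unsat: float                   # unsaturations per chain
    n_oh: float                      # hydroxylations per chain
    x_ether: float
    x_ester: float
    x_amide: float
    x_cc: float
    x_gdgt: float                    # fraction of half-chains from GDGTs
    rings_per_gdgt: float | None
    formula_ipl: ChemicalFormula
    formula_headgroup: ChemicalFormula
    formula_backbone: ChemicalFormula
    formula_chain: ChemicalFormula
    zc_ipl: float
    zc_headgroup: float | None
    zc_backbone: float
    zc_chain: float
    zc_ipl_molar_mean: float         # diagnostic: naive weighted mean

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "n_c": self.n_c,
            "n_unsat": self.n_unsat,
            "n_oh": self.n_oh,
            "x_ether": self.x_ether,
            "x_ester": self.x_ester,
            "x_amide": self.x_amide,
            "x_cc": self.x_cc,
            "x_gdgt": self.x_gdgt,
            "rings_per_gdgt": self.rings_per_gdgt,
            "zc_ipl": float(self.zc_ipl),
            "zc_headgroup": (
                None if self.zc_headgroup is None else float(self.zc_headgroup)
            ),
            "zc_backbone": float(self.zc_backbone),
            "zc_chain": float(self.zc_chain),
            "zc_ipl_molar_mean": float(self.zc_ipl_molar_mean),
        }
        for comp in COMPONENTS:
            d[f"formula_{comp}"] = str(getattr(self, f"formula_{comp}"))
        return d


def summarize_sample(records: Sequence[IplRecord]) -> SampleSummary:
    """All weighted properties and component Z_C values for one sample."""
    if not records:
        raise ValueError("cannot summarize an empty sample")
    if any(r.x is None for r in records):
        raise ValueError("records are not quantified; run mole_fractions first")
    x = [r.x for r in records]
    parts = [assemble(r.spec) for r in records]
    specs = [r.spec for r in records]

    n_chains = [s.n_chains for s in specs]
    ones = [1] * len(records)

    def chain_prop(fn):
        return weighted_property(
            [sum(fn(c) for c in s.chains) for s in specs], n_chains, x
        )

    def link_frac(linkage):
        return chain_prop(lambda c: 1 if c.linkage == linkage else 0)

    fm_ipl = weighted_formula([p.full for p in parts], ones, x)
    fm_head = weighted_formula(
        [_fsum(p.headgroups) for p in parts],
        [s.n_headgroups for s in specs], x,
    )
    fm_back = weighted_formula(
        [_fsum(p.backbones) for p in parts],
        [s.n_backbones for s in specs], x,
    )
    fm_chain = weighted_formula(
        [_fsum(p.chains) for p in parts], n_chains, x
    )

    return SampleSummary(
        sample_id=records[0].sample_id,
        n_c=chain_prop(lambda c: c.n_c),
        n_unsat=chain_prop(lambda c: c.n_unsat),
        n_oh=chain_prop(lambda c: c.n_oh),
        x_ether=link_frac("ether"),
        x_ester=link_frac("ester"),
        x_amide=link_frac("amide"),
        x_cc=link_frac("cc"),
        x_gdgt=chain_prop(lambda c: 1 if c.is_gdgt_half else 0),
        rings_per_gdgt=rings_per_gdgt(records),
        formula_ipl=fm_ipl,
        formula_headgroup=fm_head,
        formula_backbone=fm_back,
        formula_chain=fm_chain,
        zc_ipl=zc(fm_ipl),
        zc_headgroup=zc(fm_head) if fm_head.c > 0 else None,
        zc_backbone=zc(fm_back),
        zc_chain=zc(fm_chain),
        zc_ipl_molar_mean=sum(
            xi * float(zc(p.full)) for xi, p in zip(x, parts)
        ),
    )


def _fsum(formulas) -> ChemicalFormula:
    out = ChemicalFormula()
    for f in formulas:
        out = out + f
    return out


def summarize_dataset(
    quantified: dict[str, Sequence[IplRecord]]
) -> dict[str, SampleSummary]:
    """Summarize every sample of a quantified dataset."""
    return {sid: summarize_sample(recs) for sid, recs in quantified.items()}
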