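"""Intact-polar-lipid structural accounting.

An IPL is partitioned into three building blocks — headgroup(s), glycerol
(or glycerol-like) backbone(s), and alkyl chains — with strict boundaries so
that elemental formulae and per-chain properties (nC, nUnsat, nOH, linkage)
are comparable across widely different lipid classes:

* the backbone is a three-carbon unit carrying the three "connector" groups
  (ester/ether O, amide NH, or a methylene for a C-C link) that anchor the
  headgroup and the chains;
* alkyl chains begin at the carbon directly after the connector atom and run
  to the terminal methyl;
* membrane-spanning tetraethers (GDGTs) count as two backbones, two
  headgroups and four twenty-carbon half-chains, so their chain properties
  average against those of bilayer lipids.  The second GDGT headgroup may be
  the carbon-free hydroxyl hydrogen "H".

Annotation strings follow the field's shorthand, ``HEAD-BACKBONE(C:U)``:
``PC-DAG(32:0)``, ``SQ-DAG(34:1)``, ``2G-P-AR(40:0)`` (archaeol, a diether
with isoprenoid chains), ``1G-GDGT(2)`` (two internal rings).  Total chain
carbons are split across chains as evenly as possible; per-chain syntax
``(16:0/18:1)`` overrides.  Hydroxylations are flagged ``;OH`` and
cyclopropane rings in non-GDGT chains are encoded as unsaturations.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources

from .chem import ChemicalFormula, parse_formula

__all__ = [
    "ChainSpec",
    "LipidSpec",
    "ComponentFormulas",
    "HEADGROUPS",
    "BACKBONES",
    "parse_ipl_name",
    "headgroup_formula",
    "backbone_formula",
    "chain_formula",
    "assemble",
    "canonical_name",
]

LINKAGES = ("ester", "ether", "amide", "cc")


def _load_csv(name: str) -> list[dict]:
    with resources.files("lipidzc.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


#: Headgroup registry: code -> (formula, category).  Formulae are the
#: elemental abundances of the headgroup portion alone, protonated so the
#: full lipid is neutral; permanent quaternary-ammonium charges (PC, BL,
#: TM-KL, TM-OL) are carried as +1.
HEADGROUPS: dict[str, dict] = {
    row["code"]: {
        "formula": parse_formula(row["formula"]),
        "category": row["category"],
    }
    for row in _load_csv("headgroups.csv")
}

#: Backbone registry: class -> per-backbone formula, backbone multiplicity
#: and default chain-linkage pattern.  The non-glycerol backbones (CER, DIOL,
#: FA-OH-FAm, FA-OH-FAm-OH) use figure-derived default formulae satisfying
#: the three-carbon/three-connector rule.
BACKBONES: dict[str, dict] = {
    row["class"]: {
        "formula": parse_formula(row["formula"]),
        "n_backbones": int(row["n_backbones"]),
        "linkages": tuple(row["linkages"].split("|")),
    }
    for row in _load_csv("backbones.csv")
}


@dataclass(frozen=True)
class ChainSpec:
    """One alkyl chain (or GDGT half-chain)."""

    linkage: str                # ester | ether | amide | cc
    n_c: int
    n_unsat: int = 0
    n_oh: int = 0
    is_gdgt_half: bool = False
    rings: int = 0              # internal rings, GDGT half-chains only
    isoprenoid: bool = False    # archaeol-style chain; informational

    def __post_init__(self) -> None:
        if self.linkage not in LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.n_c < 1:
            raise ValueError("chain must have at least one carbon")
        if self.n_unsat < 0 or self.n_oh < 0 or self.rings < 0:
            raise ValueError("chain modification counts must be >= 0")
        if self.n_unsat > self.n_c:
            raise ValueError("more unsaturations than carbons")
        if self.rings and not self.is_gdgt_half:
            raise ValueError("internal rings are a GDGT half-chain feature")


@dataclass(frozen=True)
class LipidSpec:
    """Parsed structural description of one IPL."""

    headgroup_codes: tuple[str, ...]
    backbone_class: str
    chains: tuple[ChainSpec, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a lipid must have at least one alkyl chain")
        for code in self.headgroup_codes:
            if code not in HEADGROUPS:
                raise ValueError(f"unknown headgroup code {code!r}")
        if self.backbone_class not in BACKBONES:
            raise ValueError(f"unknown backbone class {self.backbone_class!r}")

    @property
    def n_headgroups(self) -> int:
        return len(self.headgroup_codes)

    @property
    def n_backbones(self) -> int:
        return BACKBONES[self.backbone_class]["n_backbones"]

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def is_gdgt(self) -> bool:
        return self.backbone_class == "GDGT"

    @property
    def rings_total(self) -> int:
        """Internal rings per lipid (summed over half-chains)."""
        return sum(c.rings for c in self.chains)

    @property
    def rf_key(self) -> tuple[str, str]:
        """(headgroup, backbone-linkage) combination for response factors.

        Cardiolipin's chains are acyl, so its registry linkage row is DAG.
        """
        backbone = "DAG" if self.backbone_class == "DPG" else self.backbone_class
        return self.headgroup_codes[0], backbone


@dataclass(frozen=True)
class ComponentFormulas:
    """Exact partition of a lipid's formula into its components."""

    headgroups: tuple[ChemicalFormula, ...]
    backbones: tuple[ChemicalFormula, ...]
    chains: tuple[ChemicalFormula, ...]
    full: ChemicalFormula


def headgroup_formula(code: str) -> ChemicalFormula:
    """Registry formula (with permanent charge) for a headgroup code."""
    try:
        return HEADGROUPS[code]["formula"]
    except KeyError:
        raise ValueError(f"unknown headgroup code {code!r}") from None


def backbone_formula(backbone_class: str) -> ChemicalFormula:
    """Per-backbone formula; C3H5O3 for all fully-linked glycerols."""
    try:
        return BACKBONES[backbone_class]["formula"]
    except KeyError:
        raise ValueError(f"unknown backbone class {backbone_class!r}") from None


def chain_formula(cs: ChainSpec) -> ChemicalFormula:
    """Elemental formula of one alkyl chain.

    Base formulae (connector atoms belong to the backbone):

    * ester/amide (acyl, starts at the carbonyl C): ``C_n H_(2n-1) O``
    * ether or C-C linked:                          ``C_n H_(2n+1)``
    * GDGT half-chain (ether one end, C-C to its
      partner half-chain on the other):             ``C_n H_(2n)``

    then -2 H per unsaturation or internal ring and +1 O per hydroxylation.
    """
    n = cs.n_c
    if cs.is_gdgt_half:
        h = 2 * n
    elif cs.linkage in ("ester", "amide"):
        h = 2 * n - 1
    else:  # ether, cc
        h = 2 * n + 1
    o = 1 if cs.linkage in ("ester", "amide") else 0
    h -= 2 * (cs.n_unsat + cs.rings)
    if h < 0:
        raise ValueError(f"chain {cs} would have negative hydrogen count")
    return ChemicalFormula(c=n, h=h, o=o + cs.n_oh)


def assemble(spec: LipidSpec) -> ComponentFormulas:
    """Component formulae and their exact sum for one lipid."""
    heads = tuple(headgroup_formula(c) for c in spec.headgroup_codes)
    bb = backbone_formula(spec.backbone_class)
    backbones = (bb,) * spec.n_backbones
    chains = tuple(chain_formula(c) for c in spec.chains)
    full = ChemicalFormula()
    for f in heads + backbones + chains:
        full = full + f
    return ComponentFormulas(heads, backbones, chains, full)


# --------------------------------------------------------------------------
# Annotation grammar
# --------------------------------------------------------------------------

# Longest-first so FA-OH-FAm-OH wins over FA-OH-FAm.
_BACKBONE_TOKENS = (
    "FA-OH-FAm-OH", "FA-OH-FAm", "GDGT", "DIOL", "DAG", "DEG", "AEG",
    "CER", "AR",
)

_NAME_RE = re.compile(r"^(?P<stem>[^()]+?)\((?P<args>[^()]*)\)$")
_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")

#: Headgroups whose DAG variant carries a third, headgroup-attached chain.
_THREE_CHAIN_HEADS = {"NAcG-P", "2G-NAcG-G"}


def _split_even(total: int, k: int, what: str) -> list[int]:
    """Distribute ``total`` over ``k`` slots as evenly as integers allow."""
    if total < 0:
        raise ValueError(f"negative {what} total")
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def parse_ipl_name(name: str) -> LipidSpec:
    """Parse an annotation string into a :class:`LipidSpec`.

    Grammar: ``HEAD-BACKBONE(totC:totUnsat[;OH[k]])`` with per-chain
    override ``(c1:u1/c2:u2)``; GDGTs use ``HEAD-GDGT(rings)``; ``AR`` is
    archaeol, a DEG with two C20 isoprenoid ether chains (chain carbons may
    be given, e.g. ``2G-P-AR(50:0)``); a bare ``DPG(totC:totUnsat)`` or
    ``DPG-DAG(...)`` is cardiolipin with two backbones and four acyl chains.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse lipid annotation {name!r}")
    stem, args = m.group("stem"), m.group("args")

    # cardiolipin: DPG headgroup implies the two-backbone DPG class
    if stem in ("DPG", "DPG-DAG"):
        head, backbone = "DPG", "DPG"
    else:
        for token in _BACKBONE_TOKENS:
            if stem == token or stem.endswith("-" + token):
                backbone = token
                head = stem[: -(len(token) + 1)] if stem != token else ""
                break
        else:
            raise ValueError(f"no recognized backbone class in {name!r}")
        if not head:
            raise ValueError(f"missing headgroup in {name!r}")
        if head not in HEADGROUPS:
            raise ValueError(f"unknown headgroup code {head!r} in {name!r}")

    is_ar = backbone == "AR"
    if is_ar:
        backbone = "DEG"

    if backbone == "GDGT":
        # argument is the total internal ring count
        if not re.fullmatch(r"\d+", args):
            raise ValueError(
                f"GDGT annotation takes a ring count, got {args!r} in {name!r}"
            )
        rings = _split_even(int(args), 4, "ring")
        chains = tuple(
            ChainSpec("ether", 20, is_gdgt_half=True, rings=r) for r in rings
        )
        return LipidSpec((head, "H"), "GDGT", chains, name=name)

    info = BACKBONES[backbone]
    linkages = list(info["linkages"])
    if backbone == "DAG" and head in _THREE_CHAIN_HEADS:
        linkages.append("ester")  # headgroup-attached acyl chain

    parts = args.split(";")
    body = parts[0]
    n_oh_total = 0
    for extra in parts[1:]:
        extra = extra.strip()
        mo = re.fullmatch(r"OH(\d*)", extra)
        if not mo:
            raise ValueError(f"unrecognized modifier {extra!r} in {name!r}")
        n_oh_total += int(mo.group(1) or 1)

    if "/" in body:
        per_chain = []
        for tok in body.split("/"):
            mc = _CHAIN_RE.match(tok.strip())
            if not mc:
                raise ValueError(f"bad per-chain token {tok!r} in {name!r}")
            per_chain.append((int(mc.group(1)), int(mc.group(2))))
        if len(per_chain) != len(linkages):
            raise ValueError(
                f"{name!r} lists {len(per_chain)} chains; "
                f"{backbone} variant has {len(linkages)}"
            )
        carbons = [c for c, _ in per_chain]
        unsats = [u for _, u in per_chain]
    else:
        mc = _CHAIN_RE.match(body.strip())
        if not mc:
            raise ValueError(f"bad chain descriptor {body!r} in {name!r}")
        tot_c, tot_u = int(mc.group(1)), int(mc.group(2))
        k = len(linkages)
        if tot_c < k:
            raise ValueError(f"{name!r}: fewer chain carbons than chains")
        carbons = _split_even(tot_c, k, "carbon")
        unsats = _split_even(tot_u, k, "unsaturation")

    oh = _split_even(n_oh_total, len(linkages), "hydroxylation")
    chains = tuple(
        ChainSpec(
            linkage=lk,
            n_c=c,
            n_unsat=u,
            n_oh=noh,
            isoprenoid=is_ar,
        )
        for lk, c, u, noh in zip(linkages, carbons, unsats, oh)
    )
    return LipidSpec((head,), backbone, chains, name=name)


def canonical_name(spec: LipidSpec) -> str:
    """Serialize a spec back to the annotation grammar."""
    head = spec.headgroup_codes[0]
    if spec.is_gdgt:
        return f"{head}-GDGT({spec.rings_total})"
    backbone = spec.backbone_class
    if backbone == "DPG":
        stem = "DPG"
    elif all(c.isoprenoid for c in spec.chains):
        stem = f"{head}-AR"
    else:
        stem = f"{head}-{backbone}"
    tot_c = sum(c.n_c for c in spec.chains)
    tot_u = sum(c.n_unsat for c in spec.chains)
    tot_oh = sum(c.n_oh for c in spec.chains)
    suffix = f";OH{tot_oh}" if tot_oh else ""
    return f"{stem}({tot_c}:{tot_u}{suffix})"
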