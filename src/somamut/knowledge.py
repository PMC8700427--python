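"""Gene-level and variant-level knowledge tables.

Every classification rule in the pipeline is parameterised by a handful of
curated gene lists: the Cancer Gene Census (CGC) with its tier and
oncogene/TSG role annotations, the Candidate Cancer Gene Database (CCGD)
ranks, OncoKB per-variant mutation effects, a DNA-repair pathway list, a
Ras/PIK3CA signalling membership list, and the FLAGS list of frequently
mutated long genes. This module loads those tables from TSV snapshots
shipped with the package (frozen so results are reproducible offline),
validates them, and exposes a single queryable :class:`GeneKnowledgeBase`.

Symbols are normalised to uppercase and stripped of whitespace; a query for
an unknown symbol resolves to an all-``none`` record rather than an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CgcTier",
    "CgcRole",
    "CcgdRank",
    "OncoKbEffect",
    "GeneKnowledge",
    "GeneKnowledgeBase",
    "load_knowledge",
]


class CgcTier(str, enum.Enum):
    TIER1 = "tier1"
    TIER2 = "tier2"
    NONE = "none"


class CgcRole(str, enum.Enum):
    ONCOGENE = "oncogene"
    TSG = "tsg"
    DUAL = "dual"
    NONE = "none"


class CcgdRank(str, enum.Enum):
    A = "A"
    BELOW_A = "below_A"
    NONE = "none"


class OncoKbEffect(str, enum.Enum):
    GAIN_OF_FUNCTION = "gain_of_function"
    LIKELY_GAIN_OF_FUNCTION = "likely_gain_of_function"
    LOSS_OF_FUNCTION = "loss_of_function"
    LIKELY_LOSS_OF_FUNCTION = "likely_loss_of_function"
    LIKELY_NEUTRAL = "likely_neutral"
    INCONCLUSIVE = "inconclusive"
    NOT_REPORTED = "not_reported"


#: Role strings accepted in cgc.tsv, mapped onto the enum. "oncogene/TSG"
#: style dual annotations are a single distinct value, not two rows.
_ROLE_ALIASES = {
    "oncogene": CgcRole.ONCOGENE,
    "og": CgcRole.ONCOGENE,
    "tsg": CgcRole.TSG,
    "tumor suppressor": CgcRole.TSG,
    "dual": CgcRole.DUAL,
    "og/tsg": CgcRole.DUAL,
    "oncogene/tsg": CgcRole.DUAL,
    "tsg/og": CgcRole.DUAL,
}

_TIER_ALIASES = {
    "1": CgcTier.TIER1,
    "tier1": CgcTier.TIER1,
    "2": CgcTier.TIER2,
    "tier2": CgcTier.TIER2,
}


@dataclass(frozen=True)
class GeneKnowledge:
    """Aggregated annotations for one gene symbol.

    ``cgc_role`` is ``none`` iff ``cgc_tier`` is ``none``; dual-role genes
    (annotated oncogene/TSG in the census, e.g. TP53) may satisfy either
    role in the driver-combination logic.
    """

    symbol: str
    cgc_tier: CgcTier = CgcTier.NONE
    cgc_role: CgcRole = CgcRole.NONE
    ccgd_rank: CcgdRank = CcgdRank.NONE
    dna_repair: bool = False
    dna_repair_pathway: str | None = None
    ras_pik3ca_pathway: bool = False
    flags_gene: bool = False

    @property
    def in_cgc(self) -> bool:
        return self.cgc_tier is not CgcTier.NONE

    def __post_init__(self) -> None:
        if (self.cgc_role is CgcRole.NONE) != (self.cgc_tier is CgcTier.NONE):
            raise ValueError(
                f"{self.symbol}: cgc_role must be none iff cgc_tier is none "
                f"(got role={self.cgc_role.value}, tier={self.cgc_tier.value})"
            )


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


_ALL_NONE = GeneKnowledge(symbol="")


class GeneKnowledgeBase:
    """Queryable union of the five gene tables plus OncoKB variant effects."""

    def __init__(
        self,
        genes: Mapping[str, GeneKnowledge],
        oncokb_variant: Mapping[tuple[str, str], OncoKbEffect] | None = None,
        oncokb_gene: Mapping[str, OncoKbEffect] | None = None,
    ) -> None:
        self._genes = dict(genes)
        self._oncokb_variant = dict(oncokb_variant or {})
        self._oncokb_gene = dict(oncokb_gene or {})

    def get(self, symbol: str) -> GeneKnowledge:
        """Annotations for ``symbol``; unknown genes yield an all-none record."""
        sym = _norm(symbol)
        rec = self._genes.get(sym)
        if rec is None:
            return GeneKnowledge(symbol=sym)
        return rec

    def __contains__(self, symbol: str) -> bool:
        return _norm(symbol) in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def symbols(self) -> list[str]:
        return sorted(self._genes)

    # -- OncoKB ----------------------------------------------------------

    def effect_of(self, symbol: str, protein_change: str = "") -> OncoKbEffect:
        """Mutation effect for a variant, OncoKB-style.

        Variant-level entries take precedence over gene-level entries; a
        gene/variant never curated resolves to ``not_reported``. Total
        function: never raises.
        """
        sym = _norm(symbol)
        pchange = str(protein_change or "").strip()
        if pchange:
            eff = self._oncokb_variant.get((sym, pchange))
            if eff is not None:
                return eff
        return self._oncokb_gene.get(sym, OncoKbEffect.NOT_REPORTED)

    # -- persistence -----------------------------------------------------

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Render the base back to the five-table TSV schema."""
        cgc, ccgd, repair, ras, flags = [], [], [], [], []
        for sym in self.symbols():
            rec = self._genes[sym]
            if rec.in_cgc:
                cgc.append(
                    {"symbol": sym, "tier": rec.cgc_tier.value.removeprefix("tier"),
                     "role": {CgcRole.ONCOGENE: "oncogene", CgcRole.TSG: "tsg",
                              CgcRole.DUAL: "oncogene/TSG"}[rec.cgc_role]}
                )
            if rec.ccgd_rank is not CcgdRank.NONE:
                ccgd.append({"symbol": sym,
                             "rank": "A" if rec.ccgd_rank is CcgdRank.A else "B"})
            if rec.dna_repair:
                repair.append({"symbol": sym, "pathway": rec.dna_repair_pathway or ""})
            if rec.ras_pik3ca_pathway:
                ras.append({"symbol": sym})
            if rec.flags_gene:
                flags.append({"symbol": sym})
        onco = [
            {"symbol": s, "protein_change": p, "effect": e.value}
            for (s, p), e in sorted(self._oncokb_variant.items())
        ] + [
            {"symbol": s, "protein_change": "", "effect": e.value}
            for s, e in sorted(self._oncokb_gene.items())
        ]
        return {
            "cgc": pd.DataFrame(cgc, columns=["symbol", "tier", "role"]),
            "ccgd": pd.DataFrame(ccgd, columns=["symbol", "rank"]),
            "oncokb": pd.DataFrame(onco, columns=["symbol", "protein_change", "effect"]),
            "dna_repair": pd.DataFrame(repair, columns=["symbol", "pathway"]),
            "ras_pik3ca": pd.DataFrame(ras, columns=["symbol"]),
            "flags": pd.DataFrame(flags, columns=["symbol"]),
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.to_tables().items():
            df.to_csv(directory / f"{name}.tsv", sep="\t", index=False)


_TABLE_FILES = ("cgc", "ccgd", "oncokb", "dna_repair", "ras_pik3ca", "flags")


def _read_table(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.is_file():
        raise FileNotFoundError(f"knowledge table missing: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if (df["symbol"].str.strip() == "").any():
        raise ValueError(f"{path}: empty gene symbol")
    return df


def load_knowledge(source: str | Path | Mapping[str, str | Path]) -> GeneKnowledgeBase:
    """Load the knowledge base from a directory of TSVs (or a name->path map).

    Expects cgc.tsv (symbol, tier, role), ccgd.tsv (symbol, rank),
    oncokb.tsv (symbol, protein_change, effect), dna_repair.tsv
    (symbol, pathway), ras_pik3ca.tsv (symbol) and flags.tsv (symbol).
    A missing file is a fatal configuration error; a symbol listed twice in
    cgc.tsv with conflicting roles is a fatal validation error naming the
    offenders.
    """
    if isinstance(source, (str, Path)):
        paths = {name: Path(source) / f"{name}.tsv" for name in _TABLE_FILES}
    else:
        paths = {name: Path(p) for name, p in source.items()}
        for name in _TABLE_FILES:
            if name not in paths:
                raise FileNotFoundError(f"knowledge table not configured: {name}")

    cgc = _read_table(paths["cgc"], ["symbol", "tier", "role"])
    ccgd = _read_table(paths["ccgd"], ["symbol", "rank"])
    oncokb = _read_table(paths["oncokb"], ["symbol", "protein_change", "effect"])
    repair = _read_table(paths["dna_repair"], ["symbol"])
    ras = _read_table(paths["ras_pik3ca"], ["symbol"])
    flags = _read_table(paths["flags"], ["symbol"])

    roles: dict[str, CgcRole] = {}
    tiers: dict[str, CgcTier] = {}
    conflicts: list[str] = []
    for row in cgc.itertuples(index=False):
        sym = _norm(row.symbol)
        role = _ROLE_ALIASES.get(str(row.role).strip().lower())
        if role is None:
            raise ValueError(f"cgc.tsv: unknown role {row.role!r} for {sym}")
        tier = _TIER_ALIASES.get(str(row.tier).strip().lower())
        if tier is None:
            raise ValueError(f"cgc.tsv: unknown tier {row.tier!r} for {sym}")
        if sym in roles and roles[sym] is not role:
            conflicts.append(sym)
        roles[sym] = roles.get(sym, role)
        tiers.setdefault(sym, tier)
    if conflicts:
        raise ValueError(
            "cgc.tsv: duplicate symbols with conflicting roles: "
            + ", ".join(sorted(set(conflicts)))
        )

    ranks = {
        _norm(r.symbol): (CcgdRank.A if str(r.rank).strip().upper() == "A"
                          else CcgdRank.BELOW_A)
        for r in ccgd.itertuples(index=False)
    }
    repair_pathway = {
        _norm(r.symbol): (str(getattr(r, "pathway", "")).strip() or None)
        for r in repair.itertuples(index=False)
    }
    ras_set = {_norm(r.symbol) for r in ras.itertuples(index=False)}
    flags_set = {_norm(r.symbol) for r in flags.itertuples(index=False)}

    genes: dict[str, GeneKnowledge] = {}
    for sym in set(roles) | set(ranks) | set(repair_pathway) | ras_set | flags_set:
        genes[sym] = GeneKnowledge(
            symbol=sym,
            cgc_tier=tiers.get(sym, CgcTier.NONE),
            cgc_role=roles.get(sym, CgcRole.NONE),
            ccgd_rank=ranks.get(sym, CcgdRank.NONE),
            dna_repair=sym in repair_pathway,
            dna_repair_pathway=repair_pathway.get(sym),
            ras_pik3ca_pathway=sym in ras_set,
            flags_gene=sym in flags_set,
        )

    variant_effects: dict[tuple[str, str], OncoKbEffect] = {}
    gene_effects: dict[str, OncoKbEffect] = {}
    for row in oncokb.itertuples(index=False):
        sym = _norm(row.symbol)
        effect = OncoKbEffect(str(row.effect).strip())
        pchange = str(row.protein_change).strip()
        if pchange:
            variant_effects[(sym, pchange)] = effect
        else:
            gene_effects[sym] = effect

    return GeneKnowledgeBase(genes, variant_effects, gene_effects)
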