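"""Quantification of tissue-culture-induced (epi)genetic variation from metAFLP markers.

metAFLP scores the same genomic loci on two restriction platforms that share a
recognition site but differ in methylation sensitivity: Acc65I (blocked by
methylated cytosine) and KpnI (cuts regardless of methylation).  Comparing a
donor plant's band with its regenerant's band on both platforms separates
sequence changes from methylation changes at each locus:

* the KpnI/MseI band reports whether the restriction site sequence is intact,
* the Acc65I/MseI band reports "intact AND unmethylated".

Each locus therefore collapses to a 4-digit binary code ``(aD, aR, kD, kR)`` —
Acc65I band for donor and regenerant, then KpnI band for donor and regenerant —
and the 16 possible codes classify into event types: sequence variation (SV),
demethylation (DMV), de novo methylation (DNMV), no change, uninformative, or
physically inconsistent (an Acc65I band without the corresponding KpnI band).

Event counts per methylation context (CG, CHG, CHH — assigned from the
selective primer 3' extension) are expressed as percentages of informative
loci; their sum SV% + DMV% + DNMV% is the tissue-culture-induced variation
(TCIV).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Context",
    "EventClass",
    "SiteCode",
    "VariationProfile",
    "MarkerTable",
    "ContextUnassignedError",
    "EmptyContextError",
    "encode_site",
    "classify_code",
    "assign_context",
    "quantify_variation",
    "profile_regenerant",
    "read_marker_table",
    "write_profiles",
]


class Context(str, enum.Enum):
    """Cytosine methylation sequence context (H = A, C or T)."""

    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"


class EventClass(str, enum.Enum):
    NO_CHANGE_UNMETHYLATED = "NO_CHANGE_UNMETHYLATED"
    NO_CHANGE_METHYLATED = "NO_CHANGE_METHYLATED"
    SV = "SV"
    DMV = "DMV"
    DNMV = "DNMV"
    UNINFORMATIVE = "UNINFORMATIVE"
    INCONSISTENT = "INCONSISTENT"


class ContextUnassignedError(ValueError):
    """Primer 3' extension matches no context pattern."""


class EmptyContextError(ValueError):
    """No informative locus in the requested context."""


@dataclass(frozen=True)
class SiteCode:
    """One locus as the ordered quadruple (aD, aR, kD, kR) plus its context.

    Digit order is fixed: Acc65I/MseI band for donor then regenerant, followed
    by the KpnI/MseI band for donor then regenerant.
    """

    a_donor: int
    a_regenerant: int
    k_donor: int
    k_regenerant: int
    context: Context

    def __post_init__(self) -> None:
        for name in ("a_donor", "a_regenerant", "k_donor", "k_regenerant"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @property
    def code(self) -> str:
        return f"{self.a_donor}{self.a_regenerant}{self.k_donor}{self.k_regenerant}"


def encode_site(
    acc_donor: int,
    acc_regenerant: int,
    kpn_donor: int,
    kpn_regenerant: int,
    context: Context | str,
) -> SiteCode:
    """Build a :class:`SiteCode` from the four platform/individual band flags."""
    return SiteCode(acc_donor, acc_regenerant, kpn_donor, kpn_regenerant, Context(context))


# Fixed classification of the 16 codes.  Within a plant, an Acc65I band without
# a KpnI band (a=1, k=0) is contradictory: Acc65I can only cut a site KpnI also
# cuts.  A KpnI difference between donor and regenerant is a sequence change;
# with the sequence intact in both, the Acc65I difference reads out methylation.
_TRUTH_TABLE: dict[str, EventClass] = {
    "0000": EventClass.UNINFORMATIVE,
    "0011": EventClass.NO_CHANGE_METHYLATED,
    "1111": EventClass.NO_CHANGE_UNMETHYLATED,
    "0111": EventClass.DMV,
    "1011": EventClass.DNMV,
    "0001": EventClass.SV,
    "0010": EventClass.SV,
    "0101": EventClass.SV,
    "1010": EventClass.SV,
    "0100": EventClass.INCONSISTENT,
    "0110": EventClass.INCONSISTENT,
    "1000": EventClass.INCONSISTENT,
    "1001": EventClass.INCONSISTENT,
    "1100": EventClass.INCONSISTENT,
    "1101": EventClass.INCONSISTENT,
    "1110": EventClass.INCONSISTENT,
}


def classify_code(
    site: SiteCode,
    reassignment: Mapping[str, EventClass] | None = None,
) -> EventClass:
    """Classify a site code into its event type.

    ``reassignment`` overrides individual codes, so alternative published
    coding schemes can be mirrored without changing the default table.
    """
    if reassignment is not None and site.code in reassignment:
        return EventClass(reassignment[site.code])
    return _TRUTH_TABLE[site.code]


_H = set("ACT")
_AT = set("AT")


def assign_context(primer_extension: str) -> Context:
    """Map a selective primer 3' extension to its methylation context.

    Longest suffix wins: a 3' end ``C-H-G`` (H = A, C or T) is CHG, a 3' end
    ``CG`` is CG, and a 3' end of two bases from {A, T} is the asymmetric CHH
    context.  Anything else raises :class:`ContextUnassignedError`.
    """
    ext = primer_extension.strip().upper()
    if not ext or set(ext) - set("ACGT"):
        raise ContextUnassignedError(
            f"primer extension {primer_extension!r} is not a nucleotide string"
        )
    if len(ext) >= 3 and ext[-3] == "C" and ext[-2] in _H and ext[-1] == "G":
        return Context.CHG
    if len(ext) >= 2 and ext[-2:] == "CG":
        return Context.CG
    if len(ext) >= 2 and ext[-2] in _AT and ext[-1] in _AT:
        return Context.CHH
    raise ContextUnassignedError(
        f"primer extension {primer_extension!r} matches no context pattern"
    )


@dataclass(frozen=True)
class VariationProfile:
    """Per-context event percentages for one donor/regenerant comparison.

    Percentages are over informative loci (everything except UNINFORMATIVE);
    TCIV% = SV% + DMV% + DNMV%.
    """

    context: Context
    sv_pct: float
    dmv_pct: float
    dnmv_pct: float
    tciv_pct: float
    n_informative: int
    n_inconsistent: int

    def as_dict(self) -> dict:
        d = {"context": self.context.value}
        d.update(
            sv_pct=self.sv_pct,
            dmv_pct=self.dmv_pct,
            dnmv_pct=self.dnmv_pct,
            tciv_pct=self.tciv_pct,
            n_informative=self.n_informative,
            n_inconsistent=self.n_inconsistent,
        )
        return d


def quantify_variation(
    codes: Iterable[SiteCode],
    context: Context | str,
    *,
    inconsistent_as_sv: bool = False,
    reassignment: Mapping[str, EventClass] | None = None,
) -> VariationProfile:
    """Compute SV/DMV/DNMV/TCIV percentages for one context.

    The denominator is the number of informative loci: every code except
    UNINFORMATIVE, including INCONSISTENT codes (which contribute to no event
    class unless ``inconsistent_as_sv`` folds them into SV).
    """
    context = Context(context)
    counts: dict[EventClass, int] = {c: 0 for c in EventClass}
    for site in codes:
        if site.context is not context:
            continue
        counts[classify_code(site, reassignment)] += 1
    n_inc = counts[EventClass.INCONSISTENT]
    n_informative = sum(counts.values()) - counts[EventClass.UNINFORMATIVE]
    if n_informative == 0:
        raise EmptyContextError(f"no informative locus in context {context.value}")
    n_sv = counts[EventClass.SV] + (n_inc if inconsistent_as_sv else 0)
    sv = 100.0 * n_sv / n_informative
    dmv = 100.0 * counts[EventClass.DMV] / n_informative
    dnmv = 100.0 * counts[EventClass.DNMV] / n_informative
    return VariationProfile(
        context=context,
        sv_pct=sv,
        dmv_pct=dmv,
        dnmv_pct=dnmv,
        tciv_pct=sv + dmv + dnmv,
        n_informative=n_informative,
        n_inconsistent=n_inc,
    )


_META_COLS = ("locus_id", "platform", "primer_extension")
_PLATFORMS = ("ACC", "KPN")


@dataclass
class MarkerTable:
    """Zero-one marker matrix: one row per (locus, platform), one column per plant.

    ``data`` holds the columns ``locus_id``, ``platform`` (ACC = Acc65I/MseI,
    KPN = KpnI/MseI), ``primer_extension`` and one 0/1 presence column per
    individual; by convention the first individual column is the donor.
    """

    data: pd.DataFrame
    donor: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        bad = set(self.data["platform"]) - set(_PLATFORMS)
        if bad:
            raise ValueError(f"unknown platform labels: {sorted(bad)}")
        pres = self.data[self.individuals]
        if not pres.isin([0, 1]).all().all():
            raise ValueError("presence flags must be 0 or 1")
        if self.donor is None:
            self.donor = self.individuals[0]
        elif self.donor not in self.individuals:
            raise ValueError(f"donor column {self.donor!r} not in table")

    @property
    def individuals(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLS]

    @property
    def regenerants(self) -> list[str]:
        return [c for c in self.individuals if c != self.donor]

    def merge_replicates(self, groups: Mapping[str, Sequence[str]], mode: str = "or") -> "MarkerTable":
        """Collapse technical replicate columns per plant by logical OR (default) or AND."""
        if mode not in ("or", "and"):
            raise ValueError("mode must be 'or' or 'and'")
        agg = self.data[list(_META_COLS)].copy()
        for plant, cols in groups.items():
            block = self.data[list(cols)]
            agg[plant] = (block.any(axis=1) if mode == "or" else block.all(axis=1)).astype(int)
        return MarkerTable(agg)


def profile_regenerant(
    table: MarkerTable,
    regenerant: str,
    *,
    inconsistent_as_sv: bool = False,
    reassignment: Mapping[str, EventClass] | None = None,
) -> tuple[dict[Context, VariationProfile], dict]:
    """Juxtapose donor and one regenerant across both platforms.

    Returns one :class:`VariationProfile` per context that has informative
    loci, plus a QC report listing loci excluded for a missing platform,
    ambiguous context annotation, or an unassignable primer extension.
    """
    if regenerant not in table.individuals:
        raise ValueError(f"unknown regenerant column {regenerant!r}")
    donor = table.donor
    qc: dict = {"single_platform": [], "unassigned_context": [], "duplicate_rows": [], "n_inconsistent": 0}

    # vectorized ACC/KPN juxtaposition: one row per locus after the join
    df = table.data
    dup = df.duplicated(subset=["locus_id", "platform"], keep="first")
    if dup.any():
        qc["duplicate_rows"] = sorted(set(df.loc[dup, "locus_id"].astype(str)))
        df = df[~dup]
    cols = ["locus_id", "primer_extension", donor, regenerant]
    acc = df.loc[df["platform"] == "ACC", cols].set_index("locus_id")
    kpn = df.loc[df["platform"] == "KPN", cols].set_index("locus_id")
    shared = acc.index.intersection(kpn.index)
    qc["single_platform"] = sorted(
        set(acc.index.symmetric_difference(kpn.index).astype(str))
    )
    acc, kpn = acc.loc[shared], kpn.loc[shared]

    ctx_map: dict[str, Context | None] = {}
    for ext in pd.unique(acc["primer_extension"].astype(str)):
        try:
            ctx_map[ext] = assign_context(ext)
        except ContextUnassignedError:
            ctx_map[ext] = None
    contexts = acc["primer_extension"].astype(str).map(ctx_map)
    unassigned = contexts.isna()
    qc["unassigned_context"] = sorted(set(shared[unassigned].astype(str)))

    codes = [
        SiteCode(a_d, a_r, k_d, k_r, ctx)
        for a_d, a_r, k_d, k_r, ctx in zip(
            acc[donor].to_numpy()[~unassigned],
            acc[regenerant].to_numpy()[~unassigned],
            kpn[donor].to_numpy()[~unassigned],
            kpn[regenerant].to_numpy()[~unassigned],
            contexts[~unassigned],
        )
    ]
    if qc["single_platform"]:
        warnings.warn(
            f"{len(qc['single_platform'])} loci present on one platform only were excluded",
            stacklevel=2,
        )
    profiles: dict[Context, VariationProfile] = {}
    for context in Context:
        try:
            prof = quantify_variation(
                codes, context, inconsistent_as_sv=inconsistent_as_sv, reassignment=reassignment
            )
        except EmptyContextError:
            continue
        profiles[context] = prof
        qc["n_inconsistent"] += prof.n_inconsistent
    return profiles, qc


def read_marker_table(path, *, sep: str | None = None, donor: str | None = None) -> MarkerTable:
    """Read a delimited marker table (CSV/TSV autodetected unless ``sep`` given)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return MarkerTable(df, donor=donor)


def write_profiles(profiles: Mapping[str, Mapping[Context, VariationProfile]], path) -> pd.DataFrame:
    """Write per-regenerant, per-context profiles as TSV; returns the tidy frame."""
    rows = []
    for regenerant, per_ctx in profiles.items():
        for prof in per_ctx.values():
            rows.append({"regenerant": regenerant, **prof.as_dict()})
    out = pd.DataFrame(rows)
    out.to_csv(path, sep="\t", index=False)
    return out
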