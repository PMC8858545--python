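"""Animal x feature matrix construction with CRLB quality control.

Quantified MRS results arrive in long format: one row per (animal, region,
metabolite) with a concentration and its Cramér–Rao lower bound expressed
as %SD (the per-fit uncertainty metric of linear-combination quantifiers).
Quality control proceeds in two steps:

1. *measurement filter* — a measurement is kept iff its CRLB %SD is at or
   below a threshold (default 50%); filtered cells become missing, never
   zero or imputed;
2. *metabolite inclusion* — a (region, metabolite) column enters the
   statistical analysis only if enough individuals survive the filter
   (default: at least 5 per genotype group).

Derived features (tCr = Cr + PCr, Glx = Gln + Glu, and the ratios
Glu/GABA, GABA/Glu, NAA/tCr, PCr/tCr) are computed per animal from the
filtered values; a derived cell is missing whenever any component is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METABOLITES",
    "REGIONS",
    "DERIVED_FEATURES",
    "apply_crlb_filter",
    "metabolite_inclusion",
    "derive_features",
]

#: The 17-metabolite vocabulary quantified from each voxel.
METABOLITES = (
    "Ala", "Asp", "Cr", "PCr", "GABA", "Glc", "Gln", "Glu", "GSH",
    "GPC", "Lac", "Ins", "NAA", "NAAG", "PCh", "Scyllo", "Tau",
)

REGIONS = ("PFC", "HPC")

#: name -> (kind, components); sums need all parts, ratios a positive denominator
DERIVED_FEATURES = {
    "tCr": ("sum", ("Cr", "PCr")),
    "Glx": ("sum", ("Gln", "Glu")),
    "Glu/GABA": ("ratio", ("Glu", "GABA")),
    "GABA/Glu": ("ratio", ("GABA", "Glu")),
    "NAA/tCr": ("ratio", ("NAA", "tCr")),
    "PCr/tCr": ("ratio", ("PCr", "tCr")),
}

_REQUIRED = ("id", "region", "metabolite", "concentration", "crlb_pct")


def _validate(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    bad = measurements[measurements["crlb_pct"].isna()]
    if len(bad):
        rows = bad[["id", "region", "metabolite"]].to_records(index=False).tolist()
        raise ValueError(f"measurements without CRLB: {rows[:5]}")
    unknown = set(measurements["metabolite"]) - set(METABOLITES)
    if unknown:
        raise ValueError(f"unknown metabolite names: {sorted(unknown)}")
    dup = measurements.duplicated(subset=["id", "region", "metabolite"])
    if dup.any():
        raise ValueError("duplicate (animal, region, metabolite) measurements")
    return measurements


def apply_crlb_filter(
    measurements: pd.DataFrame, max_crlb_pct: float = 50.0
) -> pd.DataFrame:
    """Mark measurements with CRLB %SD above the threshold as missing.

    The rule is inclusive: a CRLB of exactly ``max_crlb_pct`` is retained.
    Returns a copy with a boolean ``retained`` column and concentration set
    to NaN on filtered rows; the filter log (dropped rows and reason) is in
    ``result.attrs["filter_log"]``.
    """
    meas = _validate(measurements).copy()
    keep = meas["crlb_pct"] <= max_crlb_pct
    meas["retained"] = keep
    log = [
        {
            "id": r["id"],
            "region": r["region"],
            "metabolite": r["metabolite"],
            "crlb_pct": r["crlb_pct"],
            "reason": f"CRLB {r['crlb_pct']:.1f}% > {max_crlb_pct:g}%",
        }
        for _, r in meas[~keep].iterrows()
    ]
    meas.loc[~keep, "concentration"] = np.nan
    meas.attrs["filter_log"] = log
    return meas


def metabolite_inclusion(
    filtered: pd.DataFrame,
    genotypes: pd.Series | dict,
    min_n: int = 5,
    mode: str = "per_group",
) -> pd.DataFrame:
    """Per-(region, metabolite) inclusion flags from surviving counts.

    Parameters
    ----------
    filtered : DataFrame
        Output of :func:`apply_crlb_filter` (must carry ``retained``).
    genotypes : Series or dict
        Mapping animal id -> genotype label.
    min_n : int
        Count threshold, default 5.
    mode : {"per_group", "total"}
        ``per_group`` (default): included iff the surviving count is
        ``>= min_n`` in *each* genotype group. ``total``: included iff the
        total surviving count is ``> min_n`` (strict, matching the literal
        "greater than" reading of the rule).

    Returns a DataFrame indexed by (region, metabolite) with per-group
    counts and an ``included`` boolean.
    """
    if mode not in ("per_group", "total"):
        raise ValueError(f"unknown inclusion mode {mode!r}")
    gmap = dict(genotypes) if not isinstance(genotypes, pd.Series) else genotypes.to_dict()
    surv = filtered[filtered["retained"]].copy()
    surv["genotype"] = surv["id"].map(gmap)
    groups = sorted(set(gmap.values()))

    rows = []
    for (region, met), sub in filtered.groupby(["region", "metabolite"], sort=True):
        ss = surv[(surv["region"] == region) & (surv["metabolite"] == met)]
        counts = {g: int((ss["genotype"] == g).sum()) for g in groups}
        total = sum(counts.values())
        if mode == "per_group":
            included = len(groups) > 0 and all(c >= min_n for c in counts.values())
        else:
            included = total > min_n
        rows.append(
            {"region": region, "metabolite": met, "n_total": total, "included": included}
            | {f"n_{g}": c for g, c in counts.items()}
        )
    return pd.DataFrame(rows).set_index(["region", "metabolite"])


def derive_features(filtered: pd.DataFrame) -> pd.DataFrame:
    """Wide animal x feature table with derived sums and ratios.

    Rows are (id, region); columns are the 17 raw metabolites plus
    tCr, Glx, Glu/GABA, GABA/Glu, NAA/tCr, PCr/tCr.  A derived cell is
    missing if any component is missing; ratios with a non-positive
    denominator are missing and logged (``result.attrs["derive_log"]``),
    never infinite.
    """
    if "retained" not in filtered.columns:
        raise ValueError("derive_features expects a CRLB-filtered table")
    wide = filtered.pivot_table(
        index=["id", "region"],
        columns="metabolite",
        values="concentration",
        aggfunc="first",
        dropna=False,
    )
    for met in METABOLITES:
        if met not in wide.columns:
            wide[met] = np.nan
    wide = wide[list(METABOLITES)]

    log = []
    for name, (kind, (a, b)) in DERIVED_FEATURES.items():
        num = wide[a]
        den = wide[b] if b in wide.columns else wide.get(b)
        if kind == "sum":
            wide[name] = num + den
        else:
            ok = den > 0
            vals = pd.Series(np.nan, index=wide.index)
            vals[ok & num.notna()] = num[ok & num.notna()] / den[ok & num.notna()]
            bad = den.notna() & (den <= 0)
            for idx in wide.index[bad]:
                log.append({"id": idx[0], "region": idx[1], "feature": name,
                            "reason": "non-positive denominator"})
            wide[name] = vals
    wide.columns.name = None
    wide.attrs["derive_log"] = log
    return wide
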