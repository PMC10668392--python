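"""Per-day treatment testing of indices and physiology with Sidak correction.

For each day (or 4-day group for the sparser physiological traits) a
two-factor cell-means model ``genotype x treatment`` is fitted and the
well-watered minus water-deficit contrast is tested per genotype with a
t statistic using the model's pooled residual variance and degrees of
freedom -- the classical factorial-ANOVA least-squares-means contrast,
which reduces exactly to a pooled two-sample t test when only one
genotype is present.  Raw p values are then Sidak-corrected over the
whole family (all days x genotypes within one trait) and summarised into
the first significant day and the number of significant days per
trait x genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def percent_reduction(reference: float, reduced: float) -> float:
    """Percent reduction of ``reduced`` relative to ``reference``."""
    return 100.0 * (reference - reduced) / reference


def test_day(
    df: pd.DataFrame,
    value_col: str,
    genotype_col: str = "genotype",
    treatment_col: str = "treatment",
    ww_label: str = "WW",
    wd_label: str = "WD",
) -> pd.DataFrame:
    """WW-WD contrast per genotype on one day's data.

    Fits the saturated two-factor cell-means model and tests the
    within-genotype treatment contrast against the pooled residual
    variance (df = N - number of non-empty cells).  Genotypes with an
    empty or single-observation cell are skipped with a reason.

    Returns a frame with columns ``genotype``, ``raw_p``, ``t``,
    ``n_ww``, ``n_wd``, ``skipped``.
    """
    sub = df[[genotype_col, treatment_col, value_col]].dropna()
    cells = sub.groupby([genotype_col, treatment_col])[value_col]
    counts = cells.count()
    means = cells.mean()
    # pooled within-cell residual variance of the saturated model
    ss = float(((sub[value_col] - cells.transform("mean")) ** 2).sum())
    df_resid = len(sub) - len(counts)
    rows = []
    for genotype in sub[genotype_col].unique():
        n_ww = int(counts.get((genotype, ww_label), 0))
        n_wd = int(counts.get((genotype, wd_label), 0))
        if n_ww < 2 or n_wd < 2:
            rows.append(
                {
                    "genotype": genotype,
                    "raw_p": np.nan,
                    "t": np.nan,
                    "n_ww": n_ww,
                    "n_wd": n_wd,
                    "skipped": "cell with < 2 observations",
                }
            )
            continue
        if df_resid <= 0 or ss == 0:
            rows.append(
                {
                    "genotype": genotype,
                    "raw_p": np.nan,
                    "t": np.nan,
                    "n_ww": n_ww,
                    "n_wd": n_wd,
                    "skipped": "no residual degrees of freedom",
                }
            )
            continue
        s2 = ss / df_resid
        delta = means[(genotype, ww_label)] - means[(genotype, wd_label)]
        se = np.sqrt(s2 * (1.0 / n_ww + 1.0 / n_wd))
        t = delta / se
        p = 2.0 * stats.t.sf(abs(t), df_resid)
        rows.append(
            {"genotype": genotype, "raw_p": p, "t": t, "n_ww": n_ww, "n_wd": n_wd, "skipped": None}
        )
    return pd.DataFrame(rows)


def sidak_adjust(p, m: int | None = None):
    """Sidak multiplicity adjustment ``1 - (1 - p)^m``, capped at 1.

    ``m`` defaults to the number of p values passed; computed through
    ``expm1``/``log1p`` so tiny p values keep full precision.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size if p.ndim else 1
    if m < 1:
        raise ValueError("family size must be >= 1")
    with np.errstate(invalid="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    out = np.clip(adj, 0.0, 1.0)
    out = np.where(np.isnan(p), np.nan, out)
    return float(out) if out.ndim == 0 else out


def group_and_split(
    df: pd.DataFrame,
    day_col: str = "day_after_V5",
    time_col: str = "timestamp",
    group_days: int = 4,
    split_hour: float = 13.0,
) -> pd.DataFrame:
    """Attach 4-day group ids and a morning/afternoon split to physiology rows.

    Days [0, 4) form group 0, [4, 8) group 1, and so on.  Records at or
    after the split hour are labelled ``afternoon`` (the boundary itself is
    afternoon), earlier ones ``morning``.
    """
    out = df.copy()
    out["day_group"] = (out[day_col] // group_days).astype(int)
    ts = pd.to_datetime(out[time_col])
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    out["time_of_day"] = np.where(hours >= split_hour, "afternoon", "morning")
    return out


def run_detection(
    df: pd.DataFrame,
    traits,
    kind: str = "index",
    alpha: float = 0.05,
    day_col: str = "day_after_V5",
    group_days: int = 4,
) -> pd.DataFrame:
    """Day-by-day (or group-by-group) detection analysis for several traits.

    ``kind='index'`` tests every day with no time-of-day split (imaging is
    mostly in the morning); ``kind='physiology'`` bins days into
    consecutive ``group_days`` groups and splits at 13:00.  The Sidak
    family is all tests within one trait.
    """
    if kind not in ("index", "physiology"):
        raise ValueError("kind must be 'index' or 'physiology'")
    if kind == "physiology":
        df = group_and_split(df, day_col=day_col, group_days=group_days)
        time_keys = ["day_group", "time_of_day"]
    else:
        time_keys = [day_col]
    results = []
    for trait in traits:
        rows = []
        for keys, day_df in df.groupby(time_keys):
            keys = keys if isinstance(keys, tuple) else (keys,)
            res = test_day(day_df, trait)
            for k, name in zip(keys, time_keys):
                res[name] = k
            rows.append(res)
        trait_res = pd.concat(rows, ignore_index=True)
        trait_res["trait"] = trait
        tested = trait_res["raw_p"].notna()
        trait_res["adjusted_p"] = np.nan
        trait_res.loc[tested, "adjusted_p"] = sidak_adjust(
            trait_res.loc[tested, "raw_p"].to_numpy(), m=int(tested.sum())
        )
        trait_res["significant"] = trait_res["adjusted_p"] < alpha
        results.append(trait_res)
    out = pd.concat(results, ignore_index=True)
    if kind == "index":
        out = out.rename(columns={day_col: "day"})
    else:
        out = out.rename(columns={"day_group": "day"})
    return out


def summarize_detection(results: pd.DataFrame) -> pd.DataFrame:
    """First significant day and count of significant days per trait x genotype."""
    rows = []
    for (trait, genotype), g in results.groupby(["trait", "genotype"]):
        sig = g[g["significant"].fillna(False)]
        rows.append(
            {
                "trait": trait,
                "genotype": genotype,
                "first_significant_day": sig["day"].min() if len(sig) else None,
                "n_significant_days": int(len(sig["day"].unique())),
            }
        )
    return pd.DataFrame(rows)
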