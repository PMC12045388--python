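"""Presentation surfaces: ranked odds-ratio tables and arm comparisons.

Outputs are plain delimited-text tables; generation is pure, so the same
inputs always produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws
from .effects import EffectEstimate
from .psm import PropensityFit

__all__ = ["rank_predictors", "compare_arms"]

_Z95 = 1.959963984540054


def _coef_frame(source, block: str) -> pd.DataFrame:
    """Coefficient table (predictor, or, lo, hi) from any supported source."""
    if isinstance(source, PropensityFit):
        df = source.coef_table()
    elif isinstance(source, PosteriorDraws):
        model = source.model
        which = "t" if block in ("treatment", "t") else "y"
        beta = model.coef_draws(source.flat, which)
        cols = model.cols_t if which == "t" else model.cols_y
        ors = np.exp(beta)
        return pd.DataFrame(
            {
                "predictor": cols,
                "or": ors.mean(axis=0),
                "lo": np.percentile(ors, 2.5, axis=0),
                "hi": np.percentile(ors, 97.5, axis=0),
            }
        )
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        raise TypeError(f"cannot rank predictors from {type(source).__name__}")
    df = df[df["column"] != "(intercept)"]
    return pd.DataFrame(
        {
            "predictor": df["column"].to_numpy(),
            "or": np.exp(df["coef"].to_numpy()),
            "lo": np.exp(df["coef"].to_numpy() - _Z95 * df["se"].to_numpy()),
            "hi": np.exp(df["coef"].to_numpy() + _Z95 * df["se"].to_numpy()),
        }
    )


def rank_predictors(source, k: int = 18, stratum: str = "all", block: str = "treatment") -> pd.DataFrame:
    """Top-k predictors ranked by |log odds ratio|, ties alphabetical.

    ``source`` may be a fitted :class:`~ttwcausal.psm.PropensityFit`, a
    coefficient DataFrame with columns (column, coef, se), or
    :class:`~ttwcausal.bayes.PosteriorDraws` (pick ``block``).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    table = _coef_frame(source, block)
    key = np.abs(np.log(table["or"].to_numpy()))
    table = table.assign(_key=key, stratum=stratum)
    table = table.sort_values(["_key", "predictor"], ascending=[False, True], kind="mergesort")
    table = table.head(k).drop(columns="_key").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["predictor", "stratum", "or", "lo", "hi", "rank"]]


def compare_arms(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Side-by-side frequentist vs Bayesian estimates per (stratum, scale).

    Adds an interval-overlap flag per row; raises when the two arms share
    no (subgroup, scale) combination.
    """
    freq = {(e.subgroup, e.scale): e for e in effects if e.arm == "frequentist"}
    bayes = {(e.subgroup, e.scale): e for e in effects if e.arm == "bayesian"}
    shared = sorted(set(freq) & set(bayes))
    if not shared:
        raise ValueError("no (stratum, scale) combination is present in both arms")
    rows = []
    for key in shared:
        f, b = freq[key], bayes[key]
        overlap = (f.lo <= b.hi) and (b.lo <= f.hi)
        rows.append(
            {
                "stratum": key[0],
                "scale": key[1],
                "freq_estimand": f.estimand,
                "freq_point": f.point,
                "freq_lo": f.lo,
                "freq_hi": f.hi,
                "bayes_estimand": b.estimand,
                "bayes_point": b.point,
                "bayes_lo": b.lo,
                "bayes_hi": b.hi,
                "intervals_overlap": overlap,
            }
        )
    return pd.DataFrame(rows)
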