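"""Evaluation protocols: garden-path activation profiles, confound
regressions of observed on predicted RTs, and decile summaries.

Garden-path pairs contrast a locally ambiguous sentence with an early
disambiguating counterpart; the model predicts lower retrieval activation
in the garden-path member at (and just after) the disambiguating word.
Corpus evaluation regresses observed mean RTs on the model's predicted RTs
with the standard surface confounds (position, length, string frequencies),
and summarizes predicted against observed RTs by deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .memory_core import ActivationParams, DeclarativeMemory
from .parser import ParseError, parse_sentence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GardenPathPair:
    """A garden-path sentence and its early-disambiguation control.

    Sentences are sequences of (word, POS) pairs (gold POS assumed);
    ``critical_word`` is the disambiguating word and must occur in both.
    """

    id: str
    garden_path: tuple
    control: tuple
    critical_word: str

    def __post_init__(self):
        for name, sent in (("garden_path", self.garden_path), ("control", self.control)):
            if self.critical_word not in [w for w, *_ in sent]:
                raise ValueError(f"critical word {self.critical_word!r} not in {name} sentence")

    def critical_index(self, which: str) -> int:
        sent = getattr(self, which)
        return [w for w, *_ in sent].index(self.critical_word)


def gardenpath_profiles(
    pairs: Sequence[GardenPathPair],
    memory: DeclarativeMemory,
    params: ActivationParams,
    spillover: int = 1,
):
    """Per-word activation profiles and critical-word differences.

    Returns ``(profiles, summary)``: a long per-word table with one row per
    (pair, condition, word), and a per-pair summary with the control minus
    garden-path activation difference at the critical word and at the
    ``spillover`` following word(s).  Parse failures are logged and the run
    continues.
    """
    prof_rows, sum_rows = [], []
    for pair in pairs:
        acts = {}
        for cond in ("garden_path", "control"):
            sent = getattr(pair, cond)
            try:
                result = parse_sentence(sent, memory, params)
                word_acts = result.word_activations
            except ParseError as err:
                log.warning("parse failure on %s/%s: %s", pair.id, cond, err)
                word_acts = [float("nan")] * len(sent)
            acts[cond] = word_acts
            for i, ((w, *_), a) in enumerate(zip(sent, word_acts)):
                prof_rows.append(
                    {"pair": pair.id, "condition": cond, "word_index": i, "word": w,
                     "mean_activation": a}
                )
        row = {"pair": pair.id, "critical_word": pair.critical_word}
        for off in range(spillover + 1):
            ig = pair.critical_index("garden_path") + off
            ic = pair.critical_index("control") + off
            diff = float("nan")
            if ig < len(acts["garden_path"]) and ic < len(acts["control"]):
                diff = acts["control"][ic] - acts["garden_path"][ig]
            row["diff_critical" if off == 0 else f"diff_spillover_{off}"] = diff
        sum_rows.append(row)
    return pd.DataFrame(prof_rows), pd.DataFrame(sum_rows)


# ---------------------------------------------------------------------------
# regression of observed on predicted RTs


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


#: full confound model: surface predictors plus the model's predicted RT
FULL_PREDICTORS = (
    "story_c", "zone_z", "position_z", "story_c:zone_z", "zone_z:position_z",
    "nchar_z", "log_freq", "nchar_z:log_freq", "log_bigram", "log_trigram",
    "predicted_rt",
)


def rt_regression(
    table: pd.DataFrame,
    predictors: Sequence[str] = FULL_PREDICTORS,
    response: str = "rt_ms",
    predicted: str = "predicted_rt_ms",
    intercept: bool = True,
) -> pd.DataFrame:
    """OLS of observed mean RTs on predicted RTs and surface confounds.

    z-scored predictors use the mean/sd of the modeled subset (the rows of
    ``table``).  Returns a coefficient table (estimate, SE, t, p; two-sided
    p from the t distribution with residual df).  Raises on rank
    deficiency, naming the collinear columns.
    """
    df = table.copy()
    cols = {}
    if "story" in df.columns:
        uniq = sorted(df["story"].unique())
        cols["story_c"] = (df["story"] != uniq[0]).astype(float) if len(uniq) > 1 else 0.0
    for raw, z in (("zone", "zone_z"), ("position", "position_z"), ("nchar", "nchar_z")):
        if raw in df.columns:
            cols[z] = _zscore(df[raw].astype(float))
    for c in ("log_freq", "log_bigram", "log_trigram"):
        if c in df.columns:
            cols[c] = df[c].astype(float)
    cols["predicted_rt"] = df[predicted].astype(float)
    base = pd.DataFrame(cols, index=df.index)
    X = pd.DataFrame(index=df.index)
    for term in predictors:
        if ":" in term:
            a, b = term.split(":")
            X[term] = base[a] * base[b]
        else:
            X[term] = base[term]
    if intercept:
        X.insert(0, "Intercept", 1.0)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.values)
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(df[response].astype(float), X).fit()
    return pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )


# ---------------------------------------------------------------------------
# decile summaries


def decile_summary(
    table: pd.DataFrame,
    split_by: str,
    observed: str = "rt_ms",
    predicted: str = "predicted_rt_ms",
    n_bins: int = 10,
):
    """Decile means/sds of observed and predicted RTs and their correlation.

    Cut-offs are quantiles of ``split_by``; tied values stay in one bin, so
    fewer than ``n_bins`` bins can result (a warning is logged).  Returns
    ``(summary, pearson_r, p_value)`` where the correlation is between the
    per-decile mean predicted and observed RTs.
    """
    df = table.copy()
    if df[split_by].nunique() < n_bins:
        log.warning("fewer than %d distinct values of %r; fewer bins", n_bins, split_by)
    bins = pd.qcut(df[split_by].rank(method="min"), n_bins, duplicates="drop")
    df["_decile"] = bins
    grouped = df.groupby("_decile", observed=True)
    summary = grouped.agg(
        n=(observed, "size"),
        cutoff=(split_by, "max"),
        observed_mean=(observed, "mean"),
        observed_sd=(observed, "std"),
        predicted_mean=(predicted, "mean"),
        predicted_sd=(predicted, "std"),
    ).reset_index(drop=True)
    if len(summary) < 2:
        return summary, float("nan"), float("nan")
    r, p = stats.pearsonr(summary["predicted_mean"], summary["observed_mean"])
    return summary, float(r), float(p)
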