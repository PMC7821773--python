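"""Permutation ANOVA of pairwise-comparison trial outcomes.

A set of comparison runs crossed over design factors (artefact removal
yes/no, C2M vs C2C, final ICP yes/no, reference specimen) yields one mean
distance per trial. A main-effects linear model decomposes the variance of
that response with type-II sums of squares — each factor adjusted for all
the others (with no interactions, type II coincides with type III) — and
inference is non-parametric: the response rows are permuted, the F
statistic of every term recomputed, and p is the fraction of permutations
reaching the observed F, with the (count+1)/(B+1) correction so the
smallest attainable p at B=999 is 0.001. Effect sizes Z standardise the
observed log-F against the permutation distribution of log-F.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AliasingError, ValidationError

__all__ = [
    "TrialTable",
    "AnovaTable",
    "anova_type2",
    "build_trial_table",
    "load_ungual_trials",
]

DEFAULT_FACTORS = ("removal", "method", "icp", "reference")


@dataclass
class TrialTable:
    """Factor-coded comparison outcomes, one row per trial.

    Required columns: the factor columns plus a numeric response
    (``mean_distance`` by default); ``sd_distance`` and ``n_points`` are
    carried through when present.
    """

    data: pd.DataFrame
    factors: tuple = DEFAULT_FACTORS
    response: str = "mean_distance"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in (*self.factors, self.response) if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table missing column(s): {missing}")
        if len(df) < 2:
            raise ValidationError("trial table needs at least 2 rows")
        y = pd.to_numeric(df[self.response], errors="coerce")
        if not np.isfinite(y).all():
            raise ValidationError(f"non-finite values in response {self.response!r}")
        df = df.copy()
        df[self.response] = y.astype(float)
        for f in self.factors:
            df[f] = df[f].astype(str)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, factors=DEFAULT_FACTORS, response="mean_distance"):
        return cls(pd.read_csv(path), factors=factors, response=response)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class AnovaTable:
    """Per-term decomposition plus Residuals and Total rows."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None = None
    terms: list = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def build_trial_table(
    records: Sequence[dict],
    factors=DEFAULT_FACTORS,
    response: str = "mean_distance",
) -> TrialTable:
    """Assemble a trial table from per-comparison records.

    Each record is a dict holding every factor plus the response (and
    optionally ``sd_distance``/``n_points``), typically built from
    :func:`morphodist.distance_field.compare` outputs. Duplicate factor
    combinations are allowed (replicate runs) with a warning.
    """
    import logging

    rows = []
    for i, rec in enumerate(records):
        missing = [k for k in (*factors, response) if k not in rec]
        if missing:
            raise ValidationError(f"record {i} missing {missing}")
        rows.append(dict(rec))
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=list(factors))
    if dup.any():
        logging.getLogger(__name__).warning(
            "%d duplicate factor combination(s) in trial table (replicates?)",
            int(dup.sum()),
        )
    return TrialTable(df, factors=tuple(factors), response=response)


def load_ungual_trials() -> TrialTable:
    """The bundled theropod-ungual comparison outcomes.

    Twelve trials comparing the fragmentary target NMV P186153 against two
    Australovenator reference unguals (AODF604 MCII-3 and MCI-2), crossed
    over artefact removal, comparison method (C2M/C2C) and final ICP.
    """
    ref = importlib.resources.files("morphodist") / "data" / "ungual_trials.csv"
    with importlib.resources.as_file(ref) as path:
        return TrialTable.from_csv(path)


def _dummy_block(values: pd.Series) -> np.ndarray:
    """Treatment (drop-first) coding over sorted levels."""
    levels = sorted(values.unique())
    return np.column_stack(
        [(values == lv).to_numpy(dtype=float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(values), 0))


def anova_type2(
    table: TrialTable,
    response: str | None = None,
    factors: Sequence[str] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnovaTable:
    """Type-II permutation ANOVA of a trial table.

    SS of each term = residual SS of the model without that term minus
    residual SS of the full main-effects model; F = term MS over residual
    MS; R^2 = SS / total SS. Permutation p-values come from ``n_permutations``
    unrestricted shuffles of the response (seeded), as (count+1)/(B+1)
    where count is the number of permuted F >= observed F; Z is the
    standardised position of log F in the permuted log-F distribution.
    """
    response = response or table.response
    factors = tuple(factors or table.factors)
    df = table.data
    y = df[response].to_numpy(dtype=float)
    n = len(y)

    blocks: dict[str, np.ndarray] = {}
    for f in factors:
        if f not in df.columns:
            raise ValidationError(f"unknown factor {f!r}")
        b = _dummy_block(df[f])
        if b.shape[1] == 0:
            raise ValidationError(f"factor {f!r} has a single level")
        blocks[f] = b

    ones = np.ones((n, 1))

    def design(terms) -> np.ndarray:
        return np.hstack([ones] + [blocks[t] for t in terms])

    X_full = design(factors)
    rank_full = np.linalg.matrix_rank(X_full)
    model_df = 0
    term_df: dict[str, int] = {}
    for f in factors:
        others = [t for t in factors if t != f]
        d = rank_full - np.linalg.matrix_rank(design(others))
        if d == 0:
            raise AliasingError(
                f"factor {f!r} is aliased with {{{', '.join(others)}}}: "
                "no degrees of freedom remain after adjustment"
            )
        term_df[f] = int(d)
        model_df += blocks[f].shape[1]
    resid_df = n - 1 - model_df
    if resid_df <= 0:
        raise ValidationError(
            f"model has no residual degrees of freedom (n={n}, model df={model_df})"
        )

    # annihilator matrices: rss(y | X) = y' (I - H) y, reusable for permutations
    def annihilator(X: np.ndarray) -> np.ndarray:
        H = X @ np.linalg.pinv(X)
        return np.eye(n) - H

    M_full = annihilator(X_full)
    M_drop = {f: annihilator(design([t for t in factors if t != f])) for f in factors}

    def decompose(yv: np.ndarray):
        rss_full = float(yv @ M_full @ yv)
        ss = np.array([float(yv @ M_drop[f] @ yv) - rss_full for f in factors])
        return np.maximum(ss, 0.0), rss_full

    ss_obs, rss_full = decompose(y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ms_res = rss_full / resid_df
    dfs = np.array([term_df[f] for f in factors], dtype=float)
    constant = ss_total <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        F_obs = (ss_obs / dfs) / ms_res if ms_res > 0 else np.full(len(factors), np.nan)

    p = np.full(len(factors), np.nan)
    Z = np.full(len(factors), np.nan)
    if n_permutations > 0 and not constant and ms_res >= 0:
        rng = np.random.default_rng(seed)
        F_perm = np.empty((n_permutations, len(factors)))
        for b in range(n_permutations):
            yp = y[rng.permutation(n)]
            ss_p, rss_p = decompose(yp)
            ms_p = rss_p / resid_df
            with np.errstate(divide="ignore", invalid="ignore"):
                F_perm[b] = (ss_p / dfs) / ms_p if ms_p > 0 else np.inf
        ge = (F_perm >= F_obs[None, :] - 1e-12).sum(axis=0)
        p = (ge + 1) / (n_permutations + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logF = np.log(np.maximum(F_perm, 1e-300))
            mu, sdv = logF.mean(axis=0), logF.std(axis=0, ddof=1)
            Z = np.where(sdv > 0, (np.log(np.maximum(F_obs, 1e-300)) - mu) / sdv, np.nan)

    rows = {}
    for i, f in enumerate(factors):
        rows[f] = {
            "df": term_df[f],
            "SS": ss_obs[i],
            "MS": ss_obs[i] / term_df[f],
            "R2": ss_obs[i] / ss_total if ss_total > 0 else 0.0,
            "F": np.nan if constant else F_obs[i],
            "Z": Z[i],
            "p": p[i],
        }
    rows["Residuals"] = {
        "df": resid_df,
        "SS": rss_full,
        "MS": ms_res,
        "R2": rss_full / ss_total if ss_total > 0 else np.nan,
        "F": np.nan,
        "Z": np.nan,
        "p": np.nan,
    }
    rows["Total"] = {
        "df": n - 1,
        "SS": ss_total,
        "MS": np.nan,
        "R2": np.nan,
        "F": np.nan,
        "Z": np.nan,
        "p": np.nan,
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "term"
    return AnovaTable(
        table=out, n_permutations=n_permutations, seed=seed, terms=list(factors)
    )
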