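"""Mixed-design ANOVA battery for the interference analyses.

The workhorse is the two-factor split-plot (mixed) design: a between-subjects
group factor (4 perturbation conditions) crossed with a within-subjects block
factor (e.g. early vs. late exposure). The decomposition is the classical
one: the between stratum splits subject variation into the group effect and
subjects-within-groups error; the within stratum splits the remainder into
the block effect, the group x block interaction, and the block x
subjects-within-groups error.

Effect sizes are generalized eta squared (Bakeman's scheme for designs with
only manipulated factors): ges = SS_effect / (SS_effect + sum of all error
SS). Sphericity corrections use the Huynh-Feldt epsilon, which is identically
1 for two within-subject levels.

Model classes follow the construct-then-fit idiom: ``MixedAnova(...)`` holds
the data and design, ``.fit()`` returns a results object carrying the ANOVA
table and a ``summary()`` printer.

Unbalanced-but-complete designs are accepted; their main-effect sums of
squares use group-size-weighted means, while the within-subject error is
computed from exact residuals (valid for any complete design). All analyses
in the default pipeline are balanced, where all decompositions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    IncompleteDesignError,
    InvalidParameterError,
    UndefinedEffectSizeError,
)


def generalized_eta_squared(ss_effect: float, ss_errors: Sequence[float]) -> float:
    """Generalized eta squared: SS_effect / (SS_effect + sum of error SS)."""
    if ss_effect < 0 or any(s < 0 for s in ss_errors):
        raise InvalidParameterError("sums of squares must be non-negative")
    denom = ss_effect + float(np.sum(ss_errors))
    if denom == 0:
        raise UndefinedEffectSizeError("all sums of squares are zero")
    return float(ss_effect / denom)


def huynh_feldt_epsilon(wide: np.ndarray, n_groups: int = 1) -> float:
    """Huynh-Feldt sphericity epsilon for a subjects x levels matrix.

    ``wide`` holds one row per subject and one column per within-subject
    level; ``n_groups`` is the number of between-subject groups (the
    covariance is taken around the grand level means, which is conservative
    but standard for the split-plot HF formula). Returns exactly 1 for two
    levels, clipped to <= 1 otherwise.
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    if k < 2:
        raise InvalidParameterError("need at least two within-subject levels")
    if n < 2:
        raise InvalidParameterError("need at least two subjects")
    if k == 2:
        return 1.0
    S = np.cov(wide, rowvar=False)
    if not np.all(np.isfinite(S)):
        raise InvalidParameterError("covariance is not finite")
    # Greenhouse-Geisser epsilon from the double-centered covariance
    centered = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    eigvals = np.linalg.eigvalsh(centered)
    denom = (k - 1) * float(np.sum(eigvals**2))
    if denom == 0:
        raise InvalidParameterError("degenerate covariance (no within variance)")
    eps_gg = float(np.sum(eigvals)) ** 2 / denom
    num = n * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n - n_groups - (k - 1) * eps_gg)
    eps_hf = num / den if den != 0 else 1.0
    return float(min(eps_hf, 1.0))


def _f_and_p(ss_eff: float, df_eff: float, ss_err: float, df_err: float) -> tuple[float, float]:
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err == 0.0:
        return (0.0, 1.0) if ss_eff == 0.0 else (np.inf, 0.0)
    f = (ss_eff / df_eff) / ms_err
    return float(f), float(sps.f.sf(f, df_eff, df_err))


# --------------------------------------------------------------------------
# Mixed (split-plot) ANOVA
# --------------------------------------------------------------------------

@dataclass
class MixedAnovaResults:
    """Fitted split-plot ANOVA: effect table plus the error strata needed for
    post-hoc tests."""

    table: pd.DataFrame
    ms_error_between: float
    df_error_between: float
    ms_error_within: float
    df_error_within: float
    cell_means: pd.DataFrame
    group_n: pd.Series

    def summary(self) -> str:
        cols = ["df_num", "df_den", "ss_effect", "ss_error", "F", "p", "ges",
                "hf_epsilon", "p_hf"]
        with pd.option_context("display.float_format", "{:0.4g}".format):
            return "Mixed-design ANOVA\n" + self.table[cols].to_string()


class MixedAnova:
    """Two-factor mixed-design ANOVA (between groups x within blocks).

    Parameters
    ----------
    data : long-format DataFrame with one row per subject x within level
        (replicates within a cell are averaged first).
    dv, between, within, subject : column names.
    """

    def __init__(self, data: pd.DataFrame, dv: str, between: str, within: str, subject: str):
        self.data = data
        self.dv = dv
        self.between = between
        self.within = within
        self.subject = subject

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, between: str, within: str,
                       subject: str) -> "MixedAnova":
        return cls(data, dv, between, within, subject)

    def fit(self) -> MixedAnovaResults:
        d = self.data[[self.subject, self.between, self.within, self.dv]].dropna()
        cellwise = d.groupby([self.subject, self.between, self.within], sort=True)[
            self.dv
        ].mean()
        wide = cellwise.unstack(self.within)
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()
            raise IncompleteDesignError(f"subjects missing within levels: {missing[:5]}")
        groups = wide.index.get_level_values(self.between)
        level_names = list(wide.columns)
        k = len(level_names)
        group_levels = pd.unique(groups)
        g = len(group_levels)
        if g < 2:
            raise IncompleteDesignError("need at least two between-subject groups")
        group_n = pd.Series(
            [int((groups == gl).sum()) for gl in group_levels], index=group_levels
        )
        if (group_n < 2).any():
            raise IncompleteDesignError("need at least two subjects per group")
        Y = wide.to_numpy(dtype=float)
        n_total = Y.shape[0]

        grand = Y.mean()
        subj_mean = Y.mean(axis=1)
        block_mean = Y.mean(axis=0)
        group_mean = np.array([Y[groups == gl].mean() for gl in group_levels])
        cell_mean = np.vstack([Y[groups == gl].mean(axis=0) for gl in group_levels])

        ss_total = float(((Y - grand) ** 2).sum())
        ss_subj = float(k * ((subj_mean - grand) ** 2).sum())
        ss_group = float(k * (group_n.to_numpy() * (group_mean - grand) ** 2).sum())
        ss_err_b = max(ss_subj - ss_group, 0.0)
        ss_block = float(n_total * ((block_mean - grand) ** 2).sum())
        ss_int = float(
            (
                group_n.to_numpy()[:, None]
                * (cell_mean - group_mean[:, None] - block_mean[None, :] + grand) ** 2
            ).sum()
        )
        # exact within-subject residual: valid for any complete design
        lookup = {gl: i for i, gl in enumerate(group_levels)}
        gidx = np.array([lookup[gl] for gl in groups])
        resid = Y - subj_mean[:, None] - cell_mean[gidx] + group_mean[gidx][:, None]
        ss_err_w = float((resid**2).sum())

        df_group, df_err_b = g - 1, n_total - g
        df_block = k - 1
        df_int = (g - 1) * (k - 1)
        df_err_w = (n_total - g) * (k - 1)

        eps = huynh_feldt_epsilon(Y, n_groups=g) if k > 2 else 1.0

        rows = []
        errors_all = (ss_err_b, ss_err_w)
        for name, ss_eff, df_eff, ss_err, df_err, within_stratum in (
            (self.between, ss_group, df_group, ss_err_b, df_err_b, False),
            (self.within, ss_block, df_block, ss_err_w, df_err_w, True),
            (f"{self.between}:{self.within}", ss_int, df_int, ss_err_w, df_err_w, True),
        ):
            f, p = _f_and_p(ss_eff, df_eff, ss_err, df_err)
            if within_stratum and np.isfinite(f) and f > 0:
                p_hf = float(sps.f.sf(f, eps * df_eff, eps * df_err))
            else:
                p_hf = p
            rows.append(
                {
                    "effect": name,
                    "df_num": df_eff,
                    "df_den": df_err,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                    "F": f,
                    "p": p,
                    "ges": generalized_eta_squared(ss_eff, errors_all)
                    if (ss_eff + sum(errors_all)) > 0
                    else 0.0,
                    "hf_epsilon": eps if within_stratum else np.nan,
                    "p_hf": p_hf,
                }
            )
        table = pd.DataFrame(rows).set_index("effect")
        cell_df = pd.DataFrame(cell_mean, index=pd.Index(group_levels, name=self.between),
                               columns=pd.Index(level_names, name=self.within))
        return MixedAnovaResults(
            table=table,
            ms_error_between=ss_err_b / df_err_b,
            df_error_between=df_err_b,
            ms_error_within=ss_err_w / df_err_w if df_err_w > 0 else 0.0,
            df_error_within=df_err_w,
            cell_means=cell_df,
            group_n=group_n,
        )


# --------------------------------------------------------------------------
# One-way ANOVA (simple effects)
# --------------------------------------------------------------------------

@dataclass
class OneWayAnovaResults:
    table: pd.DataFrame
    ms_error: float
    df_error: float
    group_means: pd.Series
    group_n: pd.Series

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:0.4g}".format):
            return "One-way ANOVA\n" + self.table.to_string()


class OneWayAnova:
    """Between-groups one-way ANOVA with eta-squared-style ges."""

    def __init__(self, values: Sequence[float], groups: Sequence):
        self.values = np.asarray(values, dtype=float)
        self.groups = pd.Series(list(groups))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, between: str) -> "OneWayAnova":
        return cls(data[dv].to_numpy(), data[between])

    def fit(self) -> OneWayAnovaResults:
        levels = pd.unique(self.groups)
        if len(levels) < 2:
            raise IncompleteDesignError("need at least two groups")
        parts = [self.values[(self.groups == gl).to_numpy()] for gl in levels]
        if any(len(p) < 2 for p in parts):
            raise IncompleteDesignError("need at least two values per group")
        grand = self.values.mean()
        ss_b = float(sum(len(p) * (p.mean() - grand) ** 2 for p in parts))
        ss_w = float(sum(((p - p.mean()) ** 2).sum() for p in parts))
        df_b = len(levels) - 1
        df_w = len(self.values) - len(levels)
        f, p = _f_and_p(ss_b, df_b, ss_w, df_w)
        ges = (
            generalized_eta_squared(ss_b, [ss_w]) if (ss_b + ss_w) > 0 else 0.0
        )
        table = pd.DataFrame(
            [
                {
                    "effect": "group",
                    "df_num": df_b,
                    "df_den": df_w,
                    "ss_effect": ss_b,
                    "ss_error": ss_w,
                    "F": f,
                    "p": p,
                    "ges": ges,
                }
            ]
        ).set_index("effect")
        return OneWayAnovaResults(
            table=table,
            ms_error=ss_w / df_w if df_w > 0 else 0.0,
            df_error=df_w,
            group_means=pd.Series([p.mean() for p in parts], index=levels),
            group_n=pd.Series([len(p) for p in parts], index=levels),
        )


# --------------------------------------------------------------------------
# Post-hoc and t-tests
# --------------------------------------------------------------------------

def tukey_hsd(
    means: pd.Series | dict,
    ms_error: float,
    df_error: float,
    n: pd.Series | dict | int,
) -> pd.DataFrame:
    """All-pairs Tukey HSD from cell means and the ANOVA error term.

    Adjusted p-values come from the studentized range distribution with the
    family size equal to the number of cells; unequal cell sizes use the
    Tukey-Kramer standard error.
    """
    means = pd.Series(means)
    k = len(means)
    if k < 2:
        raise InvalidParameterError("need at least two cells")
    if ms_error <= 0:
        raise InvalidParameterError("MS_error must be positive")
    if isinstance(n, (int, np.integer)):
        n = pd.Series(int(n), index=means.index)
    else:
        n = pd.Series(n)
    if (n < 2).any():
        raise InvalidParameterError("need at least two observations per cell")
    rows = []
    labels = list(means.index)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = float(means[a] - means[b])
            se = np.sqrt(ms_error * 0.5 * (1.0 / n[a] + 1.0 / n[b]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_error))
            rows.append({"group_a": a, "group_b": b, "diff": diff, "q": q,
                         "p_adj": min(p_adj, 1.0)})
    return pd.DataFrame(rows)


def independent_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sided pooled-variance (Student) t-test.

    Returns (t, df, p) with df = n_a + n_b - 2. A zero pooled variance gives
    t = 0, p = 1 for equal means, and an infinite flagged t otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("need at least two values per sample")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p
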