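"""Inferential statistics for group-design behavioural tables.

Implements the classical univariate split-plot decomposition for one
between-subject factor (group) crossed with up to two within-subject
factors (typically day and light/dark phase): the between effect is
tested against subjects-within-groups, each within effect against its
subject x factor interaction.  Permutation tests exchange whole subjects
between group labels, keeping each subject's within-cell vector intact —
the only exchangeability unit that is valid for between-group effects in
a repeated-measures design.  No sphericity correction is applied; the
permutation route does not require it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Effect",
    "AnovaResult",
    "PermutationResult",
    "welch_t",
    "mixed_anova_f",
    "permutation_test",
    "holm_adjust",
    "simple_effects",
    "read_long_table",
]

DEFAULT_N_ITER = 5000


@dataclass(frozen=True)
class Effect:
    name: str
    F: float
    df1: int
    df2: int
    ss: float
    ss_error: float
    p: float  # parametric p from the F distribution


@dataclass
class AnovaResult:
    effects: dict[str, Effect] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Effect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()])


@dataclass(frozen=True)
class PermutationResult:
    effect: str
    f_obs: float
    p: float
    n_iter: int
    seed: int
    df1: int
    df2: int


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances, Satterthwaite df).

    Returns ``(t, df, p)`` with a two-tailed p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

def _design(tab: pd.DataFrame, between: str, within: list[str],
            subject: str, value: str):
    """Reshape a long table into y[subject, within-levels...] + group codes.

    Rejects unbalanced designs: every subject must be observed exactly
    once per within-cell and carry exactly one group label.
    """
    for col in [subject, between, value, *within]:
        if col not in tab.columns:
            raise ValueError(f"long table lacks column {col!r}")
    subs = tab[subject].drop_duplicates().to_list()
    g_per_sub = tab.groupby(subject, sort=False)[between].nunique()
    if (g_per_sub > 1).any():
        bad = g_per_sub[g_per_sub > 1].index[0]
        raise ValueError(f"subject {bad!r} carries more than one group label")
    levels = [np.unique(tab[w]) for w in within]
    shape = (len(subs),) + tuple(len(lv) for lv in levels)
    y = np.full(shape, np.nan)
    sub_idx = {s: i for i, s in enumerate(subs)}
    lvl_idx = [{v: i for i, v in enumerate(lv)} for lv in levels]
    counts = np.zeros(shape, dtype=int)
    for row in tab.itertuples(index=False):
        # positional access keeps arbitrary column names working
        rec = dict(zip(tab.columns, row))
        idx = (sub_idx[rec[subject]],) + tuple(
            lvl_idx[k][rec[w]] for k, w in enumerate(within))
        y[idx] = rec[value]
        counts[idx] += 1
    if not np.all(counts == 1):
        raise ValueError("unbalanced design: each subject must appear exactly "
                         "once per within-factor cell")
    glabels = tab.groupby(subject, sort=False)[between].first().reindex(subs)
    glevels = np.unique(glabels)
    gcodes = np.searchsorted(glevels, glabels.to_numpy())
    if np.min(np.bincount(gcodes)) < 2:
        raise ValueError("need at least 2 subjects per group")
    # collapse to at most 2 within factors, padding with singleton axes
    while y.ndim < 3:
        y = y[..., None]
    return y, gcodes, glevels, levels


def _safe_f(ss_eff, df1, ss_err, df2, tol):
    if df1 <= 0 or df2 <= 0:
        return None
    if ss_eff <= tol:
        return 0.0
    if ss_err <= tol:
        return float("inf")
    return float((ss_eff / df1) / (ss_err / df2))


def _anova_core(y: np.ndarray, g: np.ndarray, n_groups: int) -> dict[str, tuple]:
    """Split-plot sums of squares for y[subject, A, B] with groups g.

    Returns {effect_key: (ss_eff, df1, ss_err, df2)} with keys 'G', 'A',
    'B', 'G:A', 'G:B', 'A:B', 'G:A:B' (singleton factors omitted).
    """
    N, a, b = y.shape
    n_g = np.bincount(g, minlength=n_groups).astype(float)
    G = y.mean()
    ss_total = float(np.sum((y - G) ** 2))

    M_s = y.mean(axis=(1, 2))
    M_g = np.bincount(g, weights=M_s, minlength=n_groups) / n_g
    ss_G = a * b * float(np.sum(n_g * (M_g - G) ** 2))
    ss_S = a * b * float(np.sum((M_s - G) ** 2))
    ss_SG = ss_S - ss_G  # subjects within groups

    out = {"G": (ss_G, n_groups - 1, ss_SG, N - n_groups)}

    def within_terms(axis_means_s, axis_len, other_len):
        """Terms for one within factor from Y[s, level] margins."""
        lev_mean = axis_means_s.mean(axis=0)
        ss_F = N * other_len * float(np.sum((lev_mean - G) ** 2))
        Y_g = np.zeros((n_groups, axis_len))
        np.add.at(Y_g, g, axis_means_s)
        Y_g /= n_g[:, None]
        ss_cells_GF = other_len * float(np.sum(n_g[:, None] * (Y_g - G) ** 2))
        ss_GF = ss_cells_GF - ss_G - ss_F
        ss_cells_SF = other_len * float(np.sum((axis_means_s - G) ** 2))
        ss_err = ss_cells_SF - ss_S - ss_F - ss_GF
        return ss_F, ss_GF, ss_err

    ss_A = ss_GA = errA = 0.0
    if a > 1:
        ss_A, ss_GA, errA = within_terms(y.mean(axis=2), a, b)
        out["A"] = (ss_A, a - 1, errA, (a - 1) * (N - n_groups))
        out["G:A"] = (ss_GA, (n_groups - 1) * (a - 1), errA, (a - 1) * (N - n_groups))
    ss_B = ss_GB = errB = 0.0
    if b > 1:
        ss_B, ss_GB, errB = within_terms(y.mean(axis=1), b, a)
        out["B"] = (ss_B, b - 1, errB, (b - 1) * (N - n_groups))
        out["G:B"] = (ss_GB, (n_groups - 1) * (b - 1), errB, (b - 1) * (N - n_groups))
    if a > 1 and b > 1:
        Y_ab = y.mean(axis=0)
        ss_cells_AB = N * float(np.sum((Y_ab - G) ** 2))
        ss_AB = ss_cells_AB - ss_A - ss_B
        Y_gab = np.zeros((n_groups, a, b))
        np.add.at(Y_gab, g, y)
        Y_gab /= n_g[:, None, None]
        ss_cells_GAB = float(np.sum(n_g[:, None, None] * (Y_gab - G) ** 2))
        ss_GAB = ss_cells_GAB - ss_G - ss_A - ss_B - ss_GA - ss_GB - ss_AB
        err_AB = ss_total - (ss_S + ss_A + ss_GA + errA + ss_B + ss_GB + errB
                             + ss_AB + ss_GAB)
        dfe = (a - 1) * (b - 1) * (N - n_groups)
        out["A:B"] = (ss_AB, (a - 1) * (b - 1), err_AB, dfe)
        out["G:A:B"] = (ss_GAB, (n_groups - 1) * (a - 1) * (b - 1), err_AB, dfe)
    out["_ss_total"] = (ss_total,)
    return out


def mixed_anova_f(tab: pd.DataFrame, between: str = "group",
                  within: list[str] | None = None, subject: str = "subject",
                  value: str = "value") -> AnovaResult:
    """F decomposition for a 1-between x (0-2)-within repeated-measures design.

    ``within`` defaults to whichever of ``('day', 'phase')`` are present
    in the table.  Effects are named after the factors, e.g. ``'group'``,
    ``'day'``, ``'group:phase'``, ``'group:day:phase'``.  Constant data
    yields F = 0 for every effect; a non-zero effect over a zero error
    term reports F = inf.
    """
    if within is None:
        within = [c for c in ("day", "phase") if c in tab.columns]
    if len(within) > 2:
        raise ValueError("at most two within-subject factors are supported")
    y, gcodes, glevels, levels = _design(tab, between, list(within), subject, value)
    core = _anova_core(y, gcodes, len(glevels))
    tol = 1e-12 * max(1.0, core["_ss_total"][0])
    name_of = {"G": between}
    if len(within) >= 1:
        name_of.update({"A": within[0], "G:A": f"{between}:{within[0]}"})
    if len(within) == 2:
        name_of.update({"B": within[1], "G:B": f"{between}:{within[1]}",
                        "A:B": f"{within[0]}:{within[1]}",
                        "G:A:B": f"{between}:{within[0]}:{within[1]}"})
    result = AnovaResult()
    for key, name in name_of.items():
        if key not in core:
            continue
        ss_eff, df1, ss_err, df2 = core[key]
        F = _safe_f(ss_eff, df1, ss_err, df2, tol)
        if F is None:
            continue
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if F == 0.0:
            p = 1.0
        result.effects[name] = Effect(name, F, df1, df2, ss_eff, ss_err, p)
    return result


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _effect_key(effect: str, between: str, within: list[str]) -> str:
    parts = set(effect.split(":"))
    if between not in parts:
        raise ValueError(
            f"effect {effect!r} does not involve the between factor {between!r}; "
            "subject-level exchange cannot test purely within-subject effects")
    key = "G"
    if len(within) >= 1 and within[0] in parts:
        key += ":A"
    if len(within) == 2 and within[1] in parts:
        key += ":B"
    expect = {between} | ({within[0]} if "A" in key else set()) \
        | ({within[1]} if "B" in key else set())
    if parts != expect:
        raise ValueError(f"unknown factor in effect {effect!r}")
    return key


def permutation_test(tab: pd.DataFrame, effect: str = "group",
                     n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                     between: str = "group", within: list[str] | None = None,
                     subject: str = "subject", value: str = "value") -> PermutationResult:
    """Permutation p-value for a between-group (or group x within) effect.

    Whole subjects are exchanged between group labels uniformly at random
    each iteration (each subject's within-cell vector moves intact); the
    statistic is the split-plot F for the named effect, and
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_iter)`` (add-one estimator,
    never exactly zero).  Fully reproducible from ``seed``.
    """
    if within is None:
        within = [c for c in ("day", "phase") if c in tab.columns]
    y, gcodes, glevels, _ = _design(tab, between, list(within), subject, value)
    key = _effect_key(effect, between, list(within))
    n_groups = len(glevels)
    tol_of = lambda core: 1e-12 * max(1.0, core["_ss_total"][0])

    core = _anova_core(y, gcodes, n_groups)
    ss_eff, df1, ss_err, df2 = core[key]
    f_obs = _safe_f(ss_eff, df1, ss_err, df2, tol_of(core))

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_iter):
        perm = rng.permutation(gcodes)
        c = _anova_core(y, perm, n_groups)
        f_perm = _safe_f(*c[key][:2], *c[key][2:], tol_of(c))
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_iter)
    return PermutationResult(effect, f_obs, p, n_iter, seed, df1, df2)


# ---------------------------------------------------------------------------
# Holm step-down and simple effects
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Holm's sequentially rejective step-down adjustment.

    Sorted p-values are multiplied by (m - rank), made monotone by a
    running maximum, and capped at 1; the result is returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def simple_effects(tab: pd.DataFrame, slice_factor: str, between: str = "group",
                   within: list[str] | None = None, subject: str = "subject",
                   value: str = "value") -> pd.DataFrame:
    """Group effect re-tested within each level of ``slice_factor``.

    Each slice uses its own error term (robust to heteroscedasticity
    across phases/days); parametric p-values are Holm-corrected across
    slices.  Raises if a slice contains only one group.
    """
    if within is None:
        within = [c for c in ("day", "phase") if c in tab.columns]
    if slice_factor not in within:
        raise ValueError(f"{slice_factor!r} is not a within factor of the table")
    rest = [w for w in within if w != slice_factor]
    rows = []
    for lvl in np.unique(tab[slice_factor]):
        sub = tab[tab[slice_factor] == lvl]
        if sub[between].nunique() < 2:
            raise ValueError(f"slice {slice_factor}={lvl!r} contains a single group")
        res = mixed_anova_f(sub, between=between, within=rest,
                            subject=subject, value=value)
        eff = res[between]
        rows.append({slice_factor: lvl, "F": eff.F, "df1": eff.df1,
                     "df2": eff.df2, "p": eff.p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def read_long_table(path) -> pd.DataFrame:
    """Read a ``subject,group,day,phase,value`` CSV (day/phase optional)."""
    df = pd.read_csv(path)
    for col in ("subject", "group", "value"):
        if col not in df.columns:
            raise ValueError(f"long table CSV missing column {col!r}")
    return df
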