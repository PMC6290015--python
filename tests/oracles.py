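"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-second Python loops, explicit
orthonormal projection bases) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# per-second behavioural scans
# ---------------------------------------------------------------------------

def naive_events(d: np.ndarray, radius: float = 60.0) -> list[tuple[int, int]]:
    """Scan second by second for [onset, end) runs with d < radius that
    begin with a genuine downward crossing."""
    events = []
    inside = False
    onset = None
    for t in range(len(d)):
        if d[t] < radius and not inside:
            inside = True
            onset = t if t > 0 and d[t - 1] >= radius else None  # None: no crossing
        elif d[t] >= radius and inside:
            inside = False
            if onset is not None:
                events.append((onset, t))
            onset = None
    if inside and onset is not None:
        events.append((onset, len(d)))
    return events


def naive_huddle_bins(t: np.ndarray, d: np.ndarray, start_clock_s: int,
                      bin_s: int = 1800, radius: float = 60.0):
    """Clock-aligned bin means and huddle flags via a per-second dict scan."""
    acc: dict[int, list[float]] = {}
    first_bin = (start_clock_s + int(t[0])) // bin_s
    for k in range(len(t)):
        g = (start_clock_s + int(t[k])) // bin_s - first_bin
        acc.setdefault(g, []).append(float(d[k]))
    out = {}
    for g, vals in sorted(acc.items()):
        m = sum(vals) / len(vals)
        out[g] = (m, m < radius)
    return out


def naive_binned_mean(t: np.ndarray, v: np.ndarray, start_clock_s: int, bin_s: int):
    acc: dict[int, list[float]] = {}
    first_bin = (start_clock_s + int(t[0])) // bin_s
    for k in range(len(t)):
        g = (start_clock_s + int(t[k])) // bin_s - first_bin
        acc.setdefault(g, []).append(float(v[k]))
    return {g: sum(vals) / len(vals) for g, vals in sorted(acc.items())}


def naive_path_length(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    for k in range(1, len(x)):
        total += float(np.hypot(x[k] - x[k - 1], y[k] - y[k - 1]))
    return total


# ---------------------------------------------------------------------------
# split-plot ANOVA via explicit orthonormal projection bases
# ---------------------------------------------------------------------------

def _contrast_basis(levels: int) -> np.ndarray:
    """Orthonormal basis of the contrast space of a factor (levels x levels-1)."""
    h = np.linalg.qr(np.eye(levels) - 1.0 / levels)[0][:, :levels - 1]
    return h


def projection_anova(y: np.ndarray, n_groups: int) -> dict[str, tuple[float, int, float, int]]:
    """Split-plot SS via projections, for equal group sizes.

    ``y`` has shape (g, n, a, b) — groups x subjects-per-group x within
    levels.  Returns {effect: (ss, df, ss_err, df_err)} for the same
    effects as the implementation.
    """
    g, n, a, b = y.shape
    yv = y.reshape(-1)

    def mean_vec(k):
        return np.full((k, 1), 1.0 / np.sqrt(k))

    mg, mn, ma, mb = (mean_vec(k) for k in (g, n, a, b))
    hg, hn, ha, hb = (_contrast_basis(k) for k in (g, n, a, b))
    ig = np.eye(g)

    def kron4(A, B, C, D):
        return np.kron(np.kron(np.kron(A, B), C), D)

    def ss(basis):
        return float(np.sum((basis.T @ yv) ** 2)) if basis.shape[1] else 0.0

    bases = {
        "G": kron4(hg, mn, ma, mb),
        "S(G)": kron4(ig, hn, ma, mb),
        "A": kron4(mg, mn, ha, mb),
        "G:A": kron4(hg, mn, ha, mb),
        "A:S(G)": kron4(ig, hn, ha, mb),
        "B": kron4(mg, mn, ma, hb),
        "G:B": kron4(hg, mn, ma, hb),
        "B:S(G)": kron4(ig, hn, ma, hb),
        "A:B": kron4(mg, mn, ha, hb),
        "G:A:B": kron4(hg, mn, ha, hb),
        "A:B:S(G)": kron4(ig, hn, ha, hb),
    }
    s = {k: ss(v) for k, v in bases.items()}
    out = {"G": (s["G"], g - 1, s["S(G)"], g * (n - 1))}
    if a > 1:
        dfe = (a - 1) * g * (n - 1)
        out["A"] = (s["A"], a - 1, s["A:S(G)"], dfe)
        out["G:A"] = (s["G:A"], (g - 1) * (a - 1), s["A:S(G)"], dfe)
    if b > 1:
        dfe = (b - 1) * g * (n - 1)
        out["B"] = (s["B"], b - 1, s["B:S(G)"], dfe)
        out["G:B"] = (s["G:B"], (g - 1) * (b - 1), s["B:S(G)"], dfe)
    if a > 1 and b > 1:
        dfe = (a - 1) * (b - 1) * g * (n - 1)
        out["A:B"] = (s["A:B"], (a - 1) * (b - 1), s["A:B:S(G)"], dfe)
        out["G:A:B"] = (s["G:A:B"], (g - 1) * (a - 1) * (b - 1), s["A:B:S(G)"], dfe)
    return out


def welch_formula(x, y) -> tuple[float, float]:
    """Textbook Welch statistic and Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)
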