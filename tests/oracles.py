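"""Independent reference computations used by several test modules.

These deliberately avoid the implementation paths they check: the
biexponential oracle is an exhaustive grid search with linear amplitude
solves, not an iterative fit.
"""

import numpy as np


def grid_search_biexp(t_ms, y, n_grid=60, tau_lo=0.5, tau_hi=400.0):
    """Dense grid search over (tau_fast, tau_slow) with amplitude+offset
    solved linearly at each grid point; returns (tau_w, tau_fast, tau_slow).

    Uses precomputed Gram products so the 3x3 normal equations per pair
    are O(1).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    taus = np.geomspace(tau_lo, tau_hi, n_grid)
    E = np.exp(-t_ms[None, :] / taus[:, None])  # (n_grid, n)
    EE = E @ E.T
    Ey = E @ y
    S1 = E.sum(axis=1)
    n = t_ms.size
    ysum = float(y.sum())

    best = None
    for i in range(n_grid):
        for j in range(i, n_grid):
            G = np.array(
                [
                    [EE[i, i], EE[i, j], S1[i]],
                    [EE[i, j], EE[j, j], S1[j]],
                    [S1[i], S1[j], n],
                ]
            )
            b = np.array([Ey[i], Ey[j], ysum])
            try:
                coef = np.linalg.solve(G, b)
            except np.linalg.LinAlgError:
                continue
            # explicit residual: the Gram shortcut y'y - 2c'b + c'Gc loses
            # precision by catastrophic cancellation for near-collinear bases
            r = y - coef[0] * E[i] - coef[1] * E[j] - coef[2]
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, coef[0], taus[i], coef[1], taus[j])
    _, a_f, tau_f, a_s, tau_s = best
    wa, wb = abs(a_f), abs(a_s)
    tau_w = (wa * tau_f + wb * tau_s) / (wa + wb)
    return tau_w, tau_f, tau_s


def two_way_anova_ss(table, dv, factor_a, factor_b):
    """Classical balanced two-way ANOVA from the sums-of-squares definition.

    Returns {term: (F, df1, df2)} for the two main effects and the
    interaction. Requires a balanced complete design.
    """
    groups = table.groupby([factor_a, factor_b])[dv]
    cell_means = groups.mean()
    n_rep = groups.size().iloc[0]
    assert (groups.size() == n_rep).all(), "oracle requires balance"
    grand = table[dv].mean()
    a_means = table.groupby(factor_a)[dv].mean()
    b_means = table.groupby(factor_b)[dv].mean()
    a, b = len(a_means), len(b_means)

    ss_a = n_rep * b * float(((a_means - grand) ** 2).sum())
    ss_b = n_rep * a * float(((b_means - grand) ** 2).sum())
    ss_cells = n_rep * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((table[dv] - grand) ** 2).sum())
    ss_err = ss_total - ss_cells

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = len(table) - a * b
    ms_err = ss_err / df_err
    return {
        factor_a: (ss_a / df_a / ms_err, df_a, df_err),
        factor_b: (ss_b / df_b / ms_err, df_b, df_err),
        f"{factor_a}:{factor_b}": (ss_ab / df_ab / ms_err, df_ab, df_err),
    }
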