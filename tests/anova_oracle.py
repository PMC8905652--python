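"""Definitional sums-of-squares oracle for balanced (mixed) RM ANOVA.

Everything here is computed from marginal means by inclusion-exclusion --
no contrast matrices, no projections -- so it is an independent check on
the package's ANOVA implementation.  Balanced designs only.
"""

from __future__ import annotations

import itertools
from math import prod

import numpy as np


def _subsets(axes):
    for r in range(len(axes) + 1):
        yield from itertools.combinations(axes, r)


def _effect_array(grid: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion effect estimate on a factor grid.

    ``grid`` has one axis per factor of the effect; the returned array has
    the same shape, with the effect deviations (marginals of lower-order
    terms removed).
    """
    e = np.zeros_like(grid, dtype=float)
    k = len(axes)
    for kept in _subsets(tuple(range(grid.ndim))):
        dropped = tuple(a for a in range(grid.ndim) if a not in kept)
        term = grid.mean(axis=dropped, keepdims=True) if dropped else grid
        e = e + (-1) ** (grid.ndim - len(kept)) * term
    return e


def rm_anova_oracle(Y: np.ndarray, factor_names: list[str]) -> dict:
    """Fully within-subject ANOVA from definitions.

    ``Y`` has shape (n_subjects, k1, k2, ...) matching ``factor_names``.
    Returns {effect label: (SS_effect, SS_error, df1, df2, F)} with labels
    like ``"A"`` or ``"A * B"``.
    """
    n = Y.shape[0]
    k = Y.shape[1:]
    results = {}
    within_axes = tuple(range(1, Y.ndim))
    for effect in _subsets(within_axes):
        if not effect:
            continue
        other = tuple(a for a in within_axes if a not in effect)
        scale = prod(Y.shape[a] for a in other)
        # per-subject S-grid averages, then inclusion-exclusion
        a_i = Y.mean(axis=other) if other else Y.copy()  # (n, S-grid)
        e_i = np.stack([_effect_array(a_i[i], effect) for i in range(n)])
        e_bar = e_i.mean(axis=0)
        ss_eff = n * scale * float((e_bar ** 2).sum())
        ss_err = scale * float(((e_i - e_bar) ** 2).sum())
        df1 = prod(Y.shape[a] - 1 for a in effect)
        df2 = (n - 1) * df1
        F = (ss_eff / df1) / (ss_err / df2)
        label = " * ".join(factor_names[a - 1] for a in effect)
        results[label] = (ss_eff, ss_err, df1, df2, F)
    return results


def mixed_anova_oracle(Y_groups: list[np.ndarray], group_name: str,
                       factor_names: list[str]) -> dict:
    """Mixed ANOVA from definitions; balanced groups only.

    ``Y_groups`` holds one (n, k1, k2, ...) array per group with equal n.
    """
    ns = [Y.shape[0] for Y in Y_groups]
    assert len(set(ns)) == 1, "oracle requires balanced groups"
    n = ns[0]
    G = len(Y_groups)
    N = n * G
    K = prod(Y_groups[0].shape[1:])
    within_axes = tuple(range(1, Y_groups[0].ndim))
    results = {}

    # between-subject stratum on subject means
    subj_means = [Y.reshape(Y.shape[0], -1).mean(axis=1) for Y in Y_groups]
    gmeans = np.array([m.mean() for m in subj_means])
    grand = gmeans.mean()
    ss_g = n * K * float(((gmeans - grand) ** 2).sum())
    ss_sub = K * sum(float(((m - gm) ** 2).sum())
                     for m, gm in zip(subj_means, gmeans))
    F = (ss_g / (G - 1)) / (ss_sub / (N - G))
    results[group_name] = (ss_g, ss_sub, G - 1, N - G, F)

    for effect in _subsets(within_axes):
        if not effect:
            continue
        other = tuple(a for a in within_axes if a not in effect)
        scale = prod(Y_groups[0].shape[a] for a in other)
        df1 = prod(Y_groups[0].shape[a] - 1 for a in effect)

        e_groups = []  # per group: (n, S-grid) subject effect arrays
        for Y in Y_groups:
            a_i = Y.mean(axis=other) if other else Y.copy()
            e_groups.append(np.stack([_effect_array(a_i[i], effect)
                                      for i in range(Y.shape[0])]))
        group_bars = [e.mean(axis=0) for e in e_groups]
        grand_bar = np.mean(group_bars, axis=0)

        ss_eff = N * scale * float((grand_bar ** 2).sum())
        # group x effect: inclusion-exclusion over the group axis too
        dev = np.stack(group_bars) - grand_bar  # (G, S-grid)
        ss_int = n * scale * float((dev ** 2).sum())
        ss_err = scale * sum(float(((e - gb) ** 2).sum())
                             for e, gb in zip(e_groups, group_bars))
        df_err = (N - G) * df1
        label = " * ".join(factor_names[a - 1] for a in effect)
        F_eff = (ss_eff / df1) / (ss_err / df_err)
        F_int = (ss_int / ((G - 1) * df1)) / (ss_err / df_err)
        results[label] = (ss_eff, ss_err, df1, df_err, F_eff)
        results[f"{group_name} * {label}"] = (
            ss_int, ss_err, (G - 1) * df1, df_err, F_int)
    return results
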