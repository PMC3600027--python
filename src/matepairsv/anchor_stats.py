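"""Anchor-position correlation screening of translocations and insertions.

A genuine interchromosomal junction tiles fragments across one physical
breakpoint, so as the upstream anchor position increases the downstream
anchor must follow: a same-orientation junction implies a strong positive
Pearson correlation between the paired anchor positions, and an inverted
junction a strong negative one.  Repeat-driven artifact clusters scatter
their second anchors over the repeat and show no correlation, which is the
basis for excluding them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    expected_sign: str  # '+' or '-'
    consistent: bool
    verdict: str  # 'pass' | 'fail' | 'indeterminate'


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray,
                        method: str = "parametric",
                        n_permutations: int = 2000,
                        rng: np.random.Generator | None = None) -> tuple:
    """Pearson r with a two-sided p-value.

    parametric: t-transform of r with n-2 df.  permutation: tail frequency of
    |r| over label permutations (offered because the parametric null assumes
    bivariate normality that anchor positions need not satisfy).
    Returns (nan, nan) on n < 2 or zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if method == "permutation":
        rng = rng or np.random.default_rng(0)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        hits = 1
        for _ in range(n_permutations):
            rp = float((xc * rng.permutation(yc)).sum() / denom)
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        return r, hits / (n_permutations + 1)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(1.0, p))


def anchor_correlation(call, members, alpha: float = 0.05, min_pairs: int = 4,
                       method: str = "parametric",
                       rng: np.random.Generator | None = None
                       ) -> CorrelationResult:
    """Correlation verdict for one translocation/insertion call.

    `members` are the call's supporting MatePairRecords (or (pos1, pos2)
    tuples).  Upstream = the canonical first anchor (earlier chromosome under
    natural order, then position).  expected sign: '+' for same-orientation,
    '-' for inverted.  verdict is 'indeterminate' when n < min_pairs or a
    coordinate is degenerate, 'pass' when sign(r) matches the expectation and
    p < alpha, else 'fail'.
    """
    pos = []
    for m in members:
        if hasattr(m, "anchor1"):
            pos.append((m.anchor1.start, m.anchor2.start))
        else:
            pos.append((m[0], m[1]))
    x = np.array([p[0] for p in pos], float)
    y = np.array([p[1] for p in pos], float)
    expected_sign = "+" if call.orientation == "same" else "-"
    n = len(x)
    if n < min_pairs:
        return CorrelationResult(float("nan"), float("nan"), n, expected_sign,
                                 False, "indeterminate")
    r, p = pearson_with_pvalue(x, y, method=method, rng=rng)
    if np.isnan(r):
        return CorrelationResult(r, p, n, expected_sign, False, "indeterminate")
    sign = "+" if r > 0 else "-"
    consistent = (sign == expected_sign) and (p < alpha)
    return CorrelationResult(r, p, n, expected_sign, consistent,
                             "pass" if consistent else "fail")


def screen_translocations(calls, records_by_id: dict, alpha: float = 0.05,
                          min_pairs: int = 4, method: str = "parametric",
                          rng: np.random.Generator | None = None) -> dict:
    """Attach a CorrelationResult to every translocation and insertion call.

    Calls failing the screen get the 'correlation_fail' filter flag (a
    significant correlation of the expected sign marks a likely true
    positive).  Returns {'pass': .., 'fail': .., 'indeterminate': ..} counts.
    """
    counts = {"pass": 0, "fail": 0, "indeterminate": 0}
    for call in calls:
        if call.type not in ("translocation", "insertion"):
            continue
        members = [records_by_id[m] for m in call.members]
        result = anchor_correlation(call, members, alpha=alpha,
                                    min_pairs=min_pairs, method=method, rng=rng)
        call.correlation = result
        counts[result.verdict] += 1
        if result.verdict == "fail":
            call.filter_flags.add("correlation_fail")
    return counts
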