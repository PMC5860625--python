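"""MAX SEP: maximal pairwise subtraction of component PMFs.

Maximum-likelihood LP-ICA solutions are linearly degenerate: any invertible
non-negative recombination of the components that spans the same fitted
hyperplane has the same likelihood, so a recovered component may be a blend
of physically distinct sub-spectra.  MAX SEP resolves the degeneracy by
subtracting, for each ordered pair of components, the largest multiple of
one that can be removed from the other without driving any bin negative,
then renormalising.  Repeated over sweeps this drives the set towards
"simple structure": each component acquires zero bins where others are
large, which is the behaviour expected of genuine chemical sub-spectra
(a molecule present in one tissue class and absent in another).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lpm import ComponentPMF

__all__ = ["max_subtract", "max_sep", "simplicity_report", "SimplicityReport"]

#: subtraction leaving less than this fraction of the original mass is vetoed
MASS_FLOOR = 0.05


def max_subtract(
    target: ComponentPMF, other: ComponentPMF, mass_floor: float = MASS_FLOOR
) -> tuple[ComponentPMF, float]:
    """Subtract the maximum feasible multiple of ``other`` from ``target``.

    ``alpha = max{a >= 0 : target - a·other >= 0 in every bin}``; the result
    is renormalised to sum 1.  If the subtraction would leave less than
    ``mass_floor`` of the target's mass (near-duplicate components would
    annihilate), the target is returned unchanged with ``alpha = 0``.
    """
    t = np.asarray(target.probs, dtype=float)
    o = np.asarray(other.probs, dtype=float)
    if t.shape != o.shape:
        raise ValueError("components must share one bin dimension")
    support = o > 0
    alpha = float(np.min(t[support] / o[support])) if np.any(support) else 0.0
    if alpha <= 0:
        return target, 0.0
    remaining = 1.0 - alpha  # both PMFs sum to 1
    if remaining < mass_floor:
        return target, 0.0
    new = np.clip(t - alpha * o, 0.0, None)
    new /= new.sum()
    return ComponentPMF(new, label=target.label), alpha


def max_sep(
    components: list[ComponentPMF],
    max_sweeps: int = 100,
    tol: float = 1e-6,
    weights: np.ndarray | None = None,
    mass_floor: float = MASS_FLOOR,
) -> list[ComponentPMF]:
    """Apply maximal pairwise subtraction until no sweep changes anything.

    Ordered pairs are visited in descending order of total fitted weight
    (``weights``, one total per component, optional) so dominant structure
    is subtracted first.  Sweeps repeat until the largest subtracted
    fraction in a sweep falls below ``tol`` or ``max_sweeps`` is reached.
    Every output is a valid PMF and the non-negative span of the set is
    preserved on the fitted hyperplane.
    """
    if len(components) < 2:
        raise ValueError("max_sep needs at least 2 components")
    comps = list(components)
    K = len(comps)
    if weights is not None:
        order = list(np.argsort(-np.asarray(weights, dtype=float)))
    else:
        order = list(range(K))

    for _ in range(max_sweeps):
        largest_alpha = 0.0
        for k in order:  # dominant component being subtracted
            for j in order:
                if j == k:
                    continue
                comps[j], alpha = max_subtract(comps[j], comps[k], mass_floor)
                largest_alpha = max(largest_alpha, alpha)
        if largest_alpha < tol:
            break
    return comps


@dataclass
class SimplicityReport:
    """Diagnostic zero-structure summary of a component set.

    ``contrast[j, k]`` counts bins where component j is (near-)zero while
    component k carries a large loading (above its own mean bin
    probability).  ``criteria_satisfied`` is True when every component has
    at least K zero bins and every ordered pair shows at least one contrast
    bin — the classical simple-structure conditions adapted to PMFs.
    """

    zeros_per_component: list[int]
    contrast: np.ndarray
    criteria_satisfied: bool


def simplicity_report(
    components: list[ComponentPMF], zero_tol: float = 1e-6
) -> SimplicityReport:
    """Report per-component zero counts and pairwise contrast (diagnostic only)."""
    P = np.stack([c.probs for c in components])
    K, B = P.shape
    near_zero = P < zero_tol
    large = P > P.mean(axis=1, keepdims=True)
    zeros = [int(near_zero[k].sum()) for k in range(K)]
    contrast = np.zeros((K, K), dtype=int)
    for j in range(K):
        for k in range(K):
            if j != k:
                contrast[j, k] = int(np.sum(near_zero[j] & large[k]))
    ok = all(z >= K for z in zeros) and all(
        contrast[j, k] >= 1 for j in range(K) for k in range(K) if j != k
    )
    return SimplicityReport(zeros, contrast, ok)
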