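"""Gold-master reference implementations, for tests only.

Everything here is written directly from the model's defining equations,
deliberately sharing no arithmetic helper with the optimised recursion
module, so it can serve as an independent ground truth:

* the *unscaled* forward/backward recursions with their scaling sums
  ``F``/``G`` (usable while the unscaled probabilities stay above the
  double-precision floor, so tests keep ``L`` small);
* an independent re-derivation of the *rescaled* recursions;
* an exhaustive hidden-path posterior that literally enumerates all
  ``(N-1)^L`` copying paths (guarded to at most 10^6 paths).

None of this is optimised; correctness and independence are the point.
"""

from __future__ import annotations

import numpy as np

from .hap_cache import HaplotypeCache, query_cache
from .parameters import ModelParameters

__all__ = [
    "forward_unscaled",
    "backward_unscaled",
    "forward_rescaled_reference",
    "backward_rescaled_reference",
    "exhaustive_posterior",
]

_MAX_PATHS = 10**6


def _theta_column(
    h_row: np.ndarray, recipient: int, mu: float, use_speidel: bool
) -> np.ndarray:
    """Emission probabilities of every donor for one recipient, from the
    kernel definition (written out case by case on purpose)."""
    N = h_row.size
    hi = int(h_row[recipient])
    theta = np.empty(N)
    for j in range(N):
        hj = int(h_row[j])
        if hj == hi:
            theta[j] = 1.0 - mu
        elif use_speidel and hi == 0 and hj == 1:
            theta[j] = 1.0
        elif use_speidel:  # hi == 1, hj == 0
            theta[j] = mu
        else:
            theta[j] = mu
    return theta


def _pi_column(pars: ModelParameters, recipient: int) -> np.ndarray:
    if pars.pi is not None:
        return np.asarray(pars.pi[:, recipient], dtype=np.float64)
    col = np.full(pars.num_haps, 1.0 / (pars.num_haps - 1))
    col[recipient] = 0.0
    return col


def forward_unscaled(
    cache: HaplotypeCache,
    pars: ModelParameters,
    recipient: int,
    target_variant: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Literal unscaled forward recursion for one recipient.

    Returns ``(atilde, F)`` where ``atilde[l]`` is the unscaled forward
    column at variant ``l`` (0-based, up to the target) and ``F[l]`` its
    donor sum.  The convention ``F^0 = 1`` of the scaling identity refers to
    the slot *before* the first variant and is implicit.  Raises if a whole
    column underflows to exactly zero (instance too large for the unscaled
    recursion).
    """
    h = query_cache(cache)
    pi_col = _pi_column(pars, recipient)
    atilde = np.empty((target_variant + 1, pars.num_haps))
    F = np.empty(target_variant + 1)
    theta = _theta_column(h[0], recipient, pars.mu_at(0), pars.use_speidel)
    atilde[0] = theta * pi_col
    F[0] = atilde[0].sum()
    for ell in range(1, target_variant + 1):
        theta = _theta_column(h[ell], recipient, pars.mu_at(ell), pars.use_speidel)
        rho = pars.rho[ell - 1]
        atilde[ell] = theta * (
            (1.0 - rho) * atilde[ell - 1] + rho * F[ell - 1] * pi_col
        )
        F[ell] = atilde[ell].sum()
        if F[ell] == 0.0:
            raise FloatingPointError(
                f"unscaled forward column underflowed to zero at variant {ell}; "
                "instance too large for the unscaled reference"
            )
    return atilde, F


def backward_unscaled(
    cache: HaplotypeCache,
    pars: ModelParameters,
    recipient: int,
    target_variant: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Literal unscaled backward recursion for one recipient.

    Returns ``(btilde, G)``, each indexed by variant from ``target_variant``
    to ``L-1`` (``btilde[l - target_variant]`` is the column at variant
    ``l``); ``G[last] = 1`` by definition.
    """
    h = query_cache(cache)
    L, N = pars.num_variants, pars.num_haps
    pi_col = _pi_column(pars, recipient)
    n = L - target_variant
    btilde = np.empty((n, N))
    G = np.empty(n)
    btilde[-1] = 1.0
    G[-1] = 1.0
    for ell in range(L - 2, target_variant - 1, -1):
        k = ell - target_variant
        theta = _theta_column(
            h[ell + 1], recipient, pars.mu_at(ell + 1), pars.use_speidel
        )
        G[k] = np.sum(btilde[k + 1] * theta * pi_col)
        if G[k] == 0.0:
            raise FloatingPointError(
                f"unscaled backward scaling sum underflowed at variant {ell}; "
                "instance too large for the unscaled reference"
            )
        rho = pars.rho[ell]
        btilde[k] = (1.0 - rho) * btilde[k + 1] * theta + rho * G[k]
    return btilde, G


def forward_rescaled_reference(
    cache: HaplotypeCache,
    pars: ModelParameters,
    recipient: int,
    target_variant: int,
) -> np.ndarray:
    """Independent re-derivation of the rescaled forward recursion; returns
    the column history ``(target+1, N)``."""
    h = query_cache(cache)
    pi_col = _pi_column(pars, recipient)
    out = np.empty((target_variant + 1, pars.num_haps))
    theta = _theta_column(h[0], recipient, pars.mu_at(0), pars.use_speidel)
    out[0] = theta * pi_col
    for ell in range(1, target_variant + 1):
        theta = _theta_column(h[ell], recipient, pars.mu_at(ell), pars.use_speidel)
        rho = pars.rho[ell - 1]
        prev = out[ell - 1]
        out[ell] = theta * ((1.0 - rho) * prev / prev.sum() + rho * pi_col)
    return out


def backward_rescaled_reference(
    cache: HaplotypeCache,
    pars: ModelParameters,
    recipient: int,
    target_variant: int,
) -> np.ndarray:
    """Independent re-derivation of the rescaled backward recursion (standard
    probability space); row ``k`` is the column at variant
    ``target_variant + k``.  The self-copy (diagonal) entry is left at its
    raw recursion value; callers compare off-diagonal entries."""
    h = query_cache(cache)
    L, N = pars.num_variants, pars.num_haps
    pi_col = _pi_column(pars, recipient)
    out = np.empty((L - target_variant, N))
    out[-1] = 1.0
    for ell in range(L - 2, target_variant - 1, -1):
        k = ell - target_variant
        theta = _theta_column(
            h[ell + 1], recipient, pars.mu_at(ell + 1), pars.use_speidel
        )
        bt = out[k + 1] * theta
        g = np.sum(bt * pi_col)
        rho = pars.rho[ell]
        out[k] = (1.0 - rho) * bt / g + rho
    return out


def exhaustive_posterior(
    cache: HaplotypeCache,
    pars: ModelParameters,
    recipient: int,
    variant: int,
) -> np.ndarray:
    """Posterior copying distribution by brute-force path enumeration.

    Sums the joint weight of every hidden copying path (prior x transition x
    emission products) grouped by the donor occupied at ``variant``, then
    normalises.  Only valid for ``(N-1)**L <= 10**6``; the cost is linear in
    the number of paths.
    """
    N, L = pars.num_haps, pars.num_variants
    D = N - 1
    n_paths = D**L
    if n_paths > _MAX_PATHS:
        raise ValueError(
            f"(N-1)^L = {n_paths} exceeds {_MAX_PATHS}: instance too large "
            "for exhaustive enumeration"
        )
    h = query_cache(cache)
    donors = np.array([j for j in range(N) if j != recipient])
    prior = _pi_column(pars, recipient)[donors]
    # per-variant emission weight of each donor
    E = np.empty((L, D))
    for ell in range(L):
        E[ell] = _theta_column(
            h[ell], recipient, pars.mu_at(ell), pars.use_speidel
        )[donors]
    post = np.zeros(D)
    powers = D ** np.arange(L, dtype=np.int64)
    chunk = 1 << 17
    for start in range(0, n_paths, chunk):
        idx = np.arange(start, min(start + chunk, n_paths), dtype=np.int64)
        digits = (idx[:, None] // powers[None, :]) % D  # (paths, L)
        w = prior[digits[:, 0]].copy()
        for ell in range(L):
            w *= E[ell, digits[:, ell]]
        for ell in range(1, L):
            rho = pars.rho[ell - 1]
            same = digits[:, ell] == digits[:, ell - 1]
            w *= prior[digits[:, ell]] * rho + same * (1.0 - rho)
        post += np.bincount(digits[:, variant], weights=w, minlength=D)
    total = post.sum()
    out = np.zeros(N)
    out[donors] = post / total
    return out
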