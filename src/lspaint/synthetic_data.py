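"""Synthetic fixtures: mosaic panels drawn from the copying model itself.

The generator instantiates the HMM as a generative law.  A set of founder
haplotypes is drawn i.i.d. Bernoulli(0.5) per site (a deliberately simple
fixture with full allelic diversity, not a population-genetics claim); each
additional "copy" haplotype then samples a donor path over the founders —
switching between consecutive variants with the per-interval probability
``rho`` and resampling the donor from the prior on a switch — and emits the
donor's allele, flipped with the mis-copy probability ``mu``.  The true
donor path is retained, which is what lets decoding tests check that
posterior mass lands on the generating donor.

Also provides random recombination maps, random prior matrices and random
panel/parameter instances used throughout the test-suite sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hap_cache import cache_haplotypes, write_hap_gz, write_haps_h5
from .parameters import ModelParameters, calc_rho, make_parameters

__all__ = [
    "MosaicPanel",
    "simulate_panel",
    "random_map",
    "random_pi",
    "random_panel",
    "random_instance",
]


@dataclass(frozen=True)
class MosaicPanel:
    """A simulated panel with ground truth.

    ``haps`` is ``L x N`` (founders first, then copies); ``true_paths`` is
    ``L x N`` with the generating donor index per variant for copies and -1
    for founders; ``founder_ids`` lists the founder haplotypes.
    """

    haps: np.ndarray
    true_paths: np.ndarray
    founder_ids: np.ndarray
    seed: int

    def write(self, prefix) -> None:
        """Write the panel as ``<prefix>.hap.gz`` and ``<prefix>.h5`` plus a
        ``<prefix>.truth.tsv`` donor-path table."""
        write_hap_gz(self.haps, f"{prefix}.hap.gz")
        write_haps_h5(self.haps, f"{prefix}.h5")
        np.savetxt(
            f"{prefix}.truth.tsv",
            self.true_paths,
            fmt="%d",
            delimiter="\t",
            header="generating donor index per variant (columns = haplotypes; -1 = founder)",
        )


def _as_interval_rho(rho, L: int) -> np.ndarray:
    arr = np.asarray(rho, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(max(L - 1, 0), float(arr))
    elif arr.size == L:  # a full-length vector with the sentinel slot
        arr = arr[: L - 1]
    elif arr.size != L - 1:
        raise ValueError(f"rho must be scalar, length L-1 or L; got {arr.size}")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("rho entries must lie in [0, 1]")
    return arr


def simulate_panel(
    num_founders: int,
    num_copies: int,
    L: int,
    rho,
    mu,
    pi="uniform",
    seed: int = 0,
) -> MosaicPanel:
    """Draw a mosaic panel from the copying model.

    Founders (the first ``num_founders`` haplotypes) are i.i.d.
    Bernoulli(0.5) per site, redrawn until at least one site segregates.
    Each copy samples its donor path over the founders: the first donor from
    the prior, then per interval a switch with probability ``rho`` that
    resamples the donor from the prior (a switch may re-select the same
    donor).  Emitted alleles flip with probability ``mu`` (scalar or
    per-variant).  Fully reproducible from ``seed``.
    """
    if num_founders < 2:
        raise ValueError(f"need at least 2 founders, got {num_founders}")
    if num_copies < 0 or L < 1:
        raise ValueError("num_copies must be >= 0 and L >= 1")
    rho_iv = _as_interval_rho(rho, L)
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=np.float64), (L,))
    if ((mu_arr <= 0) | (mu_arr >= 1)).any():
        raise ValueError("mu entries must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    N = num_founders + num_copies

    founders = rng.integers(0, 2, size=(L, num_founders), dtype=np.int8)
    while L * num_founders > 1 and not (
        (founders.min(axis=1) != founders.max(axis=1)).any()
    ):
        founders = rng.integers(0, 2, size=(L, num_founders), dtype=np.int8)

    if isinstance(pi, str):
        if pi != "uniform":
            raise ValueError(f"unknown pi marker {pi!r}")
        prior = None
    else:
        prior = np.asarray(pi, dtype=np.float64)
        if prior.shape != (N, N):
            raise ValueError(f"pi must be {N}x{N}, got {prior.shape}")

    haps = np.empty((L, N), dtype=np.int8)
    haps[:, :num_founders] = founders
    true_paths = np.full((L, N), -1, dtype=np.int64)
    founder_idx = np.arange(num_founders)

    for i in range(num_founders, N):
        if prior is None:
            p = np.full(num_founders, 1.0 / num_founders)
        else:
            p = prior[founder_idx, i]
            if p.sum() <= 0:
                raise ValueError(f"pi column {i} has no mass on the founders")
            p = p / p.sum()
        path = np.empty(L, dtype=np.int64)
        path[0] = rng.choice(founder_idx, p=p)
        switch = rng.random(max(L - 1, 0)) < rho_iv
        for ell in range(1, L):
            path[ell] = rng.choice(founder_idx, p=p) if switch[ell - 1] else path[ell - 1]
        flip = rng.random(L) < mu_arr
        haps[:, i] = np.where(flip, 1 - haps[np.arange(L), path], haps[np.arange(L), path])
        true_paths[:, i] = path

    return MosaicPanel(
        haps=haps,
        true_paths=true_paths,
        founder_ids=founder_idx.copy(),
        seed=int(seed),
    )


def random_map(L: int, mean_morgans: float, seed: int = 0) -> np.ndarray:
    """I.i.d. exponential inter-variant distances (length ``L - 1``) with the
    given mean, in Morgans."""
    if mean_morgans <= 0:
        raise ValueError(f"mean_morgans must be positive, got {mean_morgans}")
    rng = np.random.default_rng(seed)
    return rng.exponential(mean_morgans, size=max(L - 1, 0))


def random_pi(N: int, seed: int = 0, concentration: float = 1.0) -> np.ndarray:
    """Random left-stochastic prior matrix: each column Dirichlet over the
    donors, zero diagonal."""
    rng = np.random.default_rng(seed)
    pi = np.zeros((N, N))
    for i in range(N):
        donors = [j for j in range(N) if j != i]
        pi[donors, i] = rng.dirichlet(np.full(N - 1, concentration))
    # make columns sum to 1 exactly after float rounding
    pi /= pi.sum(axis=0, keepdims=True)
    return pi


def random_panel(N: int, L: int, seed: int = 0) -> np.ndarray:
    """I.i.d. Bernoulli(0.5) 0/1 panel with at least one segregating site."""
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(L, N), dtype=np.int8)
    while N > 1 and not ((haps.min(axis=1) != haps.max(axis=1)).any()):
        haps = rng.integers(0, 2, size=(L, N), dtype=np.int8)
    return haps


def random_instance(
    seed: int,
    n_range: tuple[int, int] = (3, 40),
    l_range: tuple[int, int] = (1, 64),
    allow_speidel: bool = True,
):
    """A random (cache, pars) test instance: random panel, exponential map,
    random Ne/gamma, scalar or vector mu, uniform or random-matrix pi, and
    either emission model.  Used by the sweep tests and acceptance script."""
    rng = np.random.default_rng(seed)
    N = int(rng.integers(n_range[0], n_range[1] + 1))
    L = int(rng.integers(l_range[0], l_range[1] + 1))
    haps = random_panel(N, L, seed=int(rng.integers(0, 2**31 - 1)))
    cache = cache_haplotypes(haps)
    m = random_map(L, float(rng.uniform(1e-4, 0.05)), seed=int(rng.integers(0, 2**31 - 1)))
    rho = calc_rho(m, Ne=float(rng.uniform(0.5, 50.0)), gamma=float(rng.uniform(0.5, 2.0)))
    if rng.random() < 0.5:
        mu = float(rng.uniform(1e-4, 0.2))
    else:
        mu = rng.uniform(1e-4, 0.2, size=L)
    if rng.random() < 0.5:
        pi = "uniform"
    else:
        pi = random_pi(N, seed=int(rng.integers(0, 2**31 - 1)))
    use_speidel = allow_speidel and bool(rng.random() < 0.5)
    pars = make_parameters(rho, mu, pi, use_speidel=use_speidel, num_haps=N)
    return cache, pars
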