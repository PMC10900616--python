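"""Model parameters for the haplotype-copying HMM.

The model is specified by three ingredients:

* ``rho`` — per-interval donor-switch ("recombination") probabilities,
  derived from a genetic map by ``rho_l = 1 - exp(-Ne * m_l**gamma)`` where
  ``m_l`` is the interval length in Morgans, ``Ne`` the scaled effective
  population size and ``gamma`` a map-tempering exponent (default 1).
* ``mu`` — per-variant mis-copy probability (proportional to mutation rate),
  a scalar or a length-``L`` vector, strictly inside (0, 1).
* ``pi`` — the left-stochastic N x N prior copying matrix; column ``i`` is
  the prior over donors for recipient ``i``, with ``pi[i, i] == 0``.  The
  common uniform prior (1/(N-1) off-diagonal) is stored as a scalar marker
  rather than materialised.

Parameter sets are immutable and carry a SHA-256 content hash over a fixed
little-endian byte serialisation, so tables propagated under one parameter
set can refuse to continue under another.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "calc_rho",
    "make_parameters",
    "scaled_ne",
    "read_genetic_map",
    "parameters_from_config",
]

_PI_COLSUM_TOL = 1e-12


def scaled_ne(diploid_ne: float, num_haps: int) -> float:
    """Convert a diploid effective population size to the scaled quantity
    consumed by :func:`calc_rho`: ``Ne = 4 * diploid_ne / N``."""
    return 4.0 * diploid_ne / num_haps


def calc_rho(morgan_dists, Ne: float, gamma: float = 1.0) -> np.ndarray:
    """Per-interval switch probabilities from a genetic map.

    ``rho_l = 1 - exp(-Ne * m_l**gamma)``, evaluated as ``-expm1(...)`` for
    accuracy at small map distances.  Input has length ``L - 1`` (intervals
    between consecutive variants); the returned vector has length ``L`` with
    a sentinel 1.0 in the final slot, which no recursion ever consumes.
    """
    m = np.asarray(morgan_dists, dtype=np.float64)
    if m.ndim != 1:
        raise ValueError("morgan_dists must be a 1-D vector")
    if (m < 0).any():
        bad = int(np.argmax(m < 0))
        raise ValueError(f"negative genetic distance at interval {bad}: {m[bad]}")
    if not Ne > 0:
        raise ValueError(f"Ne must be positive, got {Ne}")
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    rho = np.empty(m.size + 1, dtype=np.float64)
    rho[:-1] = -np.expm1(-Ne * m**gamma)
    rho[-1] = 1.0
    return rho


@dataclass(frozen=True)
class ModelParameters:
    """Immutable LS-model parameter set with content hash.

    ``pi`` is ``None`` for the uniform prior (implied value ``1/(N-1)``
    off-diagonal, 0 diagonal) or an ``N x N`` left-stochastic matrix.
    """

    rho: np.ndarray
    mu: float | np.ndarray
    pi: np.ndarray | None
    use_speidel: bool
    num_haps: int
    num_variants: int
    content_hash: str = field(default="", compare=False)

    @property
    def mu_is_scalar(self) -> bool:
        return np.isscalar(self.mu) or np.ndim(self.mu) == 0

    def mu_at(self, variant: int) -> float:
        if self.mu_is_scalar:
            return float(self.mu)
        return float(self.mu[variant])

    def pi_columns(self, recipients: np.ndarray) -> np.ndarray:
        """Materialise prior columns for the given global recipient indices
        as an ``N x len(recipients)`` array (diagonal entries zero)."""
        recipients = np.asarray(recipients, dtype=np.intp)
        if self.pi is not None:
            return self.pi[:, recipients]
        N = self.num_haps
        cols = np.full((N, recipients.size), 1.0 / (N - 1))
        cols[recipients, np.arange(recipients.size)] = 0.0
        return cols


def _hash_parameters(rho, mu, pi, use_speidel, N, L) -> str:
    h = hashlib.sha256()
    h.update(bytes([1 if use_speidel else 0]))
    h.update(np.int64(L).astype("<i8").tobytes())
    h.update(np.int64(N).astype("<i8").tobytes())
    h.update(np.asarray(rho, dtype="<f8").tobytes())
    if np.ndim(mu) == 0:
        h.update(b"\x00")
        h.update(np.float64(mu).astype("<f8").tobytes())
    else:
        h.update(b"\x01")
        h.update(np.asarray(mu, dtype="<f8").tobytes())
    if pi is None:
        h.update(b"\x00")
    else:
        h.update(b"\x01")
        h.update(np.asarray(pi, dtype="<f8").tobytes())
    return h.hexdigest()


def make_parameters(
    rho,
    mu,
    pi="uniform",
    use_speidel: bool = False,
    num_haps: int | None = None,
) -> ModelParameters:
    """Validate and freeze a parameter set.

    Parameters
    ----------
    rho
        Length-``L`` switch-probability vector (last entry is the unused
        sentinel slot), each entry in [0, 1].
    mu
        Scalar or length-``L`` vector of mis-copy probabilities in (0, 1).
    pi
        ``"uniform"`` or an ``N x N`` matrix: non-negative, zero diagonal,
        every column summing to 1 within 1e-12.
    use_speidel
        Select the asymmetric derived-allele emission kernel.
    num_haps
        Required when ``pi`` is uniform (otherwise inferred and checked
        against the matrix shape).
    """
    rho = np.asarray(rho, dtype=np.float64).copy()
    if rho.ndim != 1 or rho.size < 1:
        raise ValueError("rho must be a 1-D vector of length L >= 1")
    L = rho.size
    if ((rho < 0) | (rho > 1)).any():
        bad = int(np.argmax((rho < 0) | (rho > 1)))
        raise ValueError(f"rho[{bad}] = {rho[bad]} outside [0, 1]")

    mu_arr = np.asarray(mu, dtype=np.float64)
    if mu_arr.ndim == 0:
        mu_val: float | np.ndarray = float(mu_arr)
        if not 0.0 < mu_val < 1.0:
            raise ValueError(f"mu = {mu_val} outside the open interval (0, 1)")
    elif mu_arr.ndim == 1:
        if mu_arr.size != L:
            raise ValueError(f"vector mu has length {mu_arr.size}, expected L={L}")
        if ((mu_arr <= 0) | (mu_arr >= 1)).any():
            bad = int(np.argmax((mu_arr <= 0) | (mu_arr >= 1)))
            raise ValueError(f"mu[{bad}] = {mu_arr[bad]} outside (0, 1)")
        mu_val = mu_arr.copy()
        mu_val.setflags(write=False)
    else:
        raise ValueError("mu must be a scalar or a length-L vector")

    if isinstance(pi, str):
        if pi != "uniform":
            raise ValueError(f"unknown pi marker {pi!r}; use 'uniform' or a matrix")
        if num_haps is None:
            raise ValueError("num_haps is required with the uniform pi marker")
        if num_haps < 2:
            raise ValueError(f"num_haps must be >= 2, got {num_haps}")
        pi_mat = None
        N = int(num_haps)
    else:
        pi_mat = np.asarray(pi, dtype=np.float64).copy()
        if pi_mat.ndim != 2 or pi_mat.shape[0] != pi_mat.shape[1]:
            raise ValueError(f"pi must be square, got shape {pi_mat.shape}")
        N = pi_mat.shape[0]
        if num_haps is not None and num_haps != N:
            raise ValueError(f"num_haps={num_haps} conflicts with pi shape {N}x{N}")
        if (pi_mat < 0).any():
            j, i = np.argwhere(pi_mat < 0)[0]
            raise ValueError(f"pi[{j}, {i}] = {pi_mat[j, i]} is negative")
        diag = np.diagonal(pi_mat)
        if (diag != 0).any():
            bad = int(np.argmax(diag != 0))
            raise ValueError(
                f"pi diagonal must be exactly 0, but pi[{bad}, {bad}] = {diag[bad]}"
            )
        colsums = pi_mat.sum(axis=0)
        off = np.abs(colsums - 1.0)
        if (off > _PI_COLSUM_TOL).any():
            bad = int(np.argmax(off > _PI_COLSUM_TOL))
            raise ValueError(
                f"pi column {bad} sums to {colsums[bad]:.15g}, expected 1"
            )
        pi_mat.setflags(write=False)

    rho.setflags(write=False)
    digest = _hash_parameters(rho, mu_val, pi_mat, use_speidel, N, L)
    return ModelParameters(
        rho=rho,
        mu=mu_val,
        pi=pi_mat,
        use_speidel=bool(use_speidel),
        num_haps=N,
        num_variants=L,
        content_hash=digest,
    )


def read_genetic_map(path, dialect: str = "interval") -> np.ndarray:
    """Read a two-column genetic map (variant id, Morgans) as interval
    distances.

    ``dialect="cumulative"`` expects L rows of cumulative positions and
    returns their successive differences (length L-1).
    ``dialect="interval"`` expects per-interval distances directly; either
    L-1 rows, or L rows whose final entry (the slot with no right-hand
    variant) is ignored.
    """
    if dialect not in ("interval", "cumulative"):
        raise ValueError(f"unknown map dialect {dialect!r}")
    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            vals.append(float(toks[1]))
    arr = np.asarray(vals, dtype=np.float64)
    if dialect == "cumulative":
        d = np.diff(arr)
        if (d < 0).any():
            raise ValueError(f"{path}: cumulative map positions must be nondecreasing")
        return d
    return arr


def parameters_from_config(path, num_haps: int, num_variants: int) -> ModelParameters:
    """Build a parameter set from a TOML config.

    Recognised keys: ``ne`` (scaled), ``gamma`` (default 1), ``mu`` (float or
    path to a one-value-per-variant text file), ``map`` (path),
    ``map_dialect`` (``"interval"``/``"cumulative"``), ``use_speidel``.
    """
    cfg = tomllib.loads(Path(path).read_text())
    base = Path(path).parent
    m = read_genetic_map(
        base / cfg["map"] if not Path(cfg["map"]).is_absolute() else cfg["map"],
        cfg.get("map_dialect", "interval"),
    )
    if m.size == num_variants:  # interval file carrying the unused final slot
        m = m[: num_variants - 1]
    if m.size != num_variants - 1:
        raise ValueError(
            f"map provides {m.size} intervals but the panel has "
            f"{num_variants} variants (needs {num_variants - 1})"
        )
    rho = calc_rho(m, Ne=float(cfg["ne"]), gamma=float(cfg.get("gamma", 1.0)))
    mu = cfg["mu"]
    if isinstance(mu, str):
        mu_path = base / mu if not Path(mu).is_absolute() else Path(mu)
        mu = np.loadtxt(mu_path, dtype=np.float64, ndmin=1)
    return make_parameters(
        rho,
        mu,
        pi="uniform",
        use_speidel=bool(cfg.get("use_speidel", False)),
        num_haps=num_haps,
    )
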