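"""Posterior copying probabilities and local genetic distance matrices.

At a variant ``l`` the posterior probability that recipient ``i`` copies
donor ``j`` is obtained by normalising the Hadamard product of the matched
forward and backward columns,

    p_{ji} = alpha_{ji} * beta_{ji} / sum_j alpha_{ji} * beta_{ji}.

If the normalising sum underflows to exactly 0, the recipient is beyond
numerical precision from every donor and the whole off-diagonal column is
set to machine epsilon (the smallest observable posterior probability).

Local distances symmetrise the negative log posterior,

    d_{ji} = -(log(p_{ji} v eps) + log(p_{ij} v eps)) / 2,   d_{ii} = 0,

where ``v`` is the binary maximum; no distance can exceed ``-log(eps)``.
Distance columns can additionally be standardised (centred/scaled by the
off-diagonal mean and sample standard deviation of each column); a column
with zero off-diagonal spread standardises to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .core_recursions import (
    BackwardTable,
    ForwardTable,
    _colsums,
    backward,
    copy_table,
)
from .hap_cache import HaplotypeCache
from .parameters import ModelParameters

__all__ = [
    "PosteriorSlice",
    "DistanceMatrix",
    "posterior",
    "distance_matrix",
    "standardise_distances",
    "write_distances_tsv",
    "read_distances_tsv",
    "write_distances_h5",
]

_EPS = float(np.finfo(np.float64).eps)  # ~2.22e-16


@dataclass(frozen=True)
class PosteriorSlice:
    """Posterior copying probabilities ``p^l`` for a recipient slice.

    Columns sum to 1 unless the degenerate rule fired (then every
    off-diagonal entry is machine epsilon); diagonal entries are 0.
    """

    probs: np.ndarray
    at_variant: int
    from_recipient: int
    to_recipient: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetrised negative-log-posterior distances at one variant."""

    dists: np.ndarray
    at_variant: int
    standardised: bool = False


def _check_match(fwd: ForwardTable, bwd: BackwardTable) -> None:
    if not (fwd.initialised and bwd.initialised):
        raise ValueError("both tables must be initialised before decoding")
    if fwd.at_variant != bwd.at_variant:
        raise ValueError(
            f"at_variant mismatch: forward at {fwd.at_variant}, backward at "
            f"{bwd.at_variant}"
        )
    if (fwd.from_recipient, fwd.to_recipient) != (
        bwd.from_recipient,
        bwd.to_recipient,
    ):
        raise ValueError(
            f"recipient slice mismatch: forward [{fwd.from_recipient}, "
            f"{fwd.to_recipient}], backward [{bwd.from_recipient}, "
            f"{bwd.to_recipient}]"
        )
    if fwd.pars_hash != bwd.pars_hash:
        raise ValueError(
            "pars_hash mismatch: forward and backward tables were propagated "
            "under different parameter sets"
        )


def posterior(
    fwd: ForwardTable,
    bwd: BackwardTable,
    pars: ModelParameters | None = None,
    cache: HaplotypeCache | None = None,
) -> PosteriorSlice:
    """Posterior copying probabilities from matched tables at one variant.

    The backward table must be in standard probability space; a table left
    in rescaled (``beta_theta``) space is completed to standard space on an
    internal copy, which requires ``pars`` and ``cache``.
    """
    _check_match(fwd, bwd)
    if bwd.beta_theta:
        if pars is None or cache is None:
            raise ValueError(
                "backward table is in rescaled (beta_theta) space; pass pars "
                "and cache so it can be completed to standard space"
            )
        bwd = backward(
            copy_table(bwd), pars, cache, bwd.at_variant, return_rescaled=False
        )
    p = fwd.alpha * bwd.beta
    denom = _colsums(p)
    recips = fwd.recipients
    local = np.arange(recips.size)
    degenerate = denom == 0.0
    safe = np.where(degenerate, 1.0, denom)
    p = p / safe
    if degenerate.any():
        p[:, degenerate] = _EPS
    p[recips, local] = 0.0
    return PosteriorSlice(
        probs=p,
        at_variant=fwd.at_variant,
        from_recipient=fwd.from_recipient,
        to_recipient=fwd.to_recipient,
    )


def distance_matrix(
    fwd: ForwardTable,
    bwd: BackwardTable,
    clamp_eps: float = _EPS,
    pars: ModelParameters | None = None,
    cache: HaplotypeCache | None = None,
) -> DistanceMatrix:
    """Symmetrised local distance matrix at the tables' variant.

    Requires full-panel tables, since ``d_{ji}`` combines ``p_{ji}`` and
    ``p_{ij}``.  Posteriors are clamped below at ``clamp_eps`` (default:
    double machine epsilon) before taking logs.
    """
    if (fwd.from_recipient, fwd.to_recipient) != (0, fwd.num_haps - 1):
        raise ValueError(
            "distance_matrix needs the full recipient range (a partial slice "
            "cannot be symmetrised)"
        )
    post = posterior(fwd, bwd, pars=pars, cache=cache)
    logp = np.log(np.maximum(post.probs, clamp_eps))
    d = -(logp + logp.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(dists=d, at_variant=post.at_variant, standardised=False)


def standardise_distances(d: DistanceMatrix) -> DistanceMatrix:
    """Centre and scale each column by the mean and sample standard
    deviation of its off-diagonal entries.

    A column whose off-diagonal standard deviation is 0 becomes all zeros.
    The diagonal stays 0.  Standardising an already standardised matrix is
    rejected.
    """
    if d.standardised:
        raise ValueError("distance matrix is already standardised")
    N = d.dists.shape[0]
    if N < 3:
        raise ValueError(
            "standardisation needs N >= 3 (off-diagonal standard deviation is "
            "degenerate with a single donor)"
        )
    out = np.empty_like(d.dists)
    off = ~np.eye(N, dtype=bool)
    for i in range(N):
        col = d.dists[off[:, i], i]
        sd = col.std(ddof=1)
        if sd == 0.0:
            out[:, i] = 0.0
        else:
            out[off[:, i], i] = (col - col.mean()) / sd
            out[i, i] = 0.0
    return DistanceMatrix(dists=out, at_variant=d.at_variant, standardised=True)


# --- writers ---------------------------------------------------------------

def write_distances_tsv(d: DistanceMatrix, path, labels=None) -> None:
    """Write the matrix as labelled TSV (variant recorded 1-based in a
    header comment)."""
    N = d.dists.shape[0]
    if labels is None:
        labels = [f"hap{j + 1}" for j in range(N)]
    with open(path, "w") as fh:
        fh.write(
            f"# variant={d.at_variant + 1} standardised={int(d.standardised)}\n"
        )
        fh.write("\t".join(["id", *labels]) + "\n")
        for j in range(N):
            vals = "\t".join(format(v, ".17g") for v in d.dists[j])
            fh.write(f"{labels[j]}\t{vals}\n")


def read_distances_tsv(path) -> DistanceMatrix:
    """Read a matrix written by :func:`write_distances_tsv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        fh.readline()  # label row
        rows = [line.split("\t")[1:] for line in fh if line.strip()]
    dists = np.asarray(rows, dtype=np.float64)
    return DistanceMatrix(
        dists=dists,
        at_variant=int(meta["variant"]) - 1,
        standardised=bool(int(meta["standardised"])),
    )


def write_distances_h5(d: DistanceMatrix, path) -> None:
    """Write the matrix to HDF5: dataset ``"distances"``, attributes
    ``variant`` (1-based) and ``standardised``."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("distances", data=d.dists)
        ds.attrs["variant"] = d.at_variant + 1
        ds.attrs["standardised"] = d.standardised
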