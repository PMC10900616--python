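"""Rescaled forward/backward recursions of the haplotype-copying HMM.

Each recipient haplotype ``i`` is the observation of an independent HMM whose
hidden state is the donor currently being copied.  The recursions here work
in the rescaled space ``alpha^l = alpha~^l / F^{l-1}`` and
``beta^l = beta~^l / G^l`` (``F``, ``G`` the running scaling sums), which
keeps every column at unit scale and defers underflow handling to the
decoding step.

Tables hold a contiguous *slice* of recipients (columns) and can be
propagated independently of the rest of the panel: column ``c`` of a table
over recipients ``[a, b]`` is bit-identical to column ``a + c`` of the
full-panel table.  Parallelism is by recipient columns, so results do not
depend on the number of workers.

Evaluation order within a step is fixed (previous column sum, then the
affine update, then the emission product) so that propagating ``k`` variants
in one call is bit-identical to ``k`` single-variant calls.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import h5py
import numpy as np

from .hap_cache import HaplotypeCache
from .parameters import ModelParameters

__all__ = [
    "ForwardTable",
    "BackwardTable",
    "make_forward_table",
    "make_backward_table",
    "emission_vector",
    "initialise_forward",
    "forward",
    "initialise_backward",
    "backward",
    "copy_table",
    "save_table",
    "load_table",
]

logger = logging.getLogger("lspaint")


@dataclass
class ForwardTable:
    """Rescaled forward probabilities for a slice of recipients.

    ``alpha`` is ``N x R`` (``R`` recipients in the slice); ``alpha_f[c]``
    is the latest pre-normalisation column sum ``sum_j alpha[j, c]`` (the
    ratio ``F^l / F^{l-1}`` of the unscaled sums).  ``at_variant`` is None
    while uninitialised.  Bounds are 0-based inclusive.
    """

    num_haps: int
    from_recipient: int
    to_recipient: int
    alpha: np.ndarray | None = None
    alpha_f: np.ndarray | None = None
    at_variant: int | None = None
    pars_hash: str | None = None

    @property
    def num_recipients(self) -> int:
        return self.to_recipient - self.from_recipient + 1

    @property
    def recipients(self) -> np.ndarray:
        return np.arange(self.from_recipient, self.to_recipient + 1)

    @property
    def initialised(self) -> bool:
        return self.at_variant is not None


@dataclass
class BackwardTable:
    """Rescaled backward probabilities for a slice of recipients.

    ``beta_theta`` records whether the stored matrix currently carries the
    emission factor of the current variant (rescaled space); a standard
    propagation step leaves it False.
    """

    num_haps: int
    from_recipient: int
    to_recipient: int
    beta: np.ndarray | None = None
    beta_g: np.ndarray | None = None
    at_variant: int | None = None
    pars_hash: str | None = None
    beta_theta: bool = False

    num_recipients = ForwardTable.num_recipients
    recipients = ForwardTable.recipients
    initialised = ForwardTable.initialised


def _colsums(mat: np.ndarray) -> np.ndarray:
    """Column sums by a fixed pairwise tree over rows.

    The associativity of the reduction depends only on the number of rows,
    never on the number of columns or the memory layout, which is what makes
    a recipient-slice propagation bit-identical to the matching columns of a
    full-table propagation (library reductions pick layout-dependent SIMD
    paths and orders).
    """
    acc = mat
    while acc.shape[0] > 1:
        n = acc.shape[0]
        k = n // 2
        if n % 2:
            acc = np.concatenate([acc[:k] + acc[k : 2 * k], acc[2 * k :]])
        else:
            acc = acc[:k] + acc[k:]
    return acc[0].copy()


def _check_bounds(num_haps: int, from_recipient: int, to_recipient: int) -> None:
    if not (0 <= from_recipient <= to_recipient < num_haps):
        raise ValueError(
            f"recipient slice [{from_recipient}, {to_recipient}] invalid for "
            f"N={num_haps} (0-based inclusive bounds required)"
        )


def make_forward_table(
    num_haps: int, from_recipient: int = 0, to_recipient: int | None = None
) -> ForwardTable:
    """Allocate an uninitialised forward table over a recipient slice."""
    if to_recipient is None:
        to_recipient = num_haps - 1
    _check_bounds(num_haps, from_recipient, to_recipient)
    return ForwardTable(num_haps, from_recipient, to_recipient)


def make_backward_table(
    num_haps: int, from_recipient: int = 0, to_recipient: int | None = None
) -> BackwardTable:
    """Allocate an uninitialised backward table over a recipient slice."""
    if to_recipient is None:
        to_recipient = num_haps - 1
    _check_bounds(num_haps, from_recipient, to_recipient)
    return BackwardTable(num_haps, from_recipient, to_recipient)


# --- emission kernels ------------------------------------------------------

def _emission_block(
    hap_row: np.ndarray,
    recip_alleles: np.ndarray,
    mu: float,
    use_speidel: bool,
) -> np.ndarray:
    """N x R emission matrix at one variant for a block of recipients.

    Symmetric kernel: ``1 - mu`` on allele match, ``mu`` on mismatch.
    Derived-allele (Relate-style) kernel: a donor carrying the derived
    allele is not penalised when the recipient is ancestral (probability 1);
    a recipient carrying the derived allele against an ancestral donor pays
    the mis-copy probability ``mu``.
    """
    eq = hap_row[:, None] == recip_alleles[None, :]
    if not use_speidel:
        return np.where(eq, 1.0 - mu, mu)
    mismatch = np.where(recip_alleles[None, :] == 1, mu, 1.0)
    return np.where(eq, 1.0 - mu, np.broadcast_to(mismatch, eq.shape))


def _emission_into(
    out: np.ndarray,
    eq: np.ndarray,
    hap_row: np.ndarray,
    recip_alleles: np.ndarray,
    mu: float,
    use_speidel: bool,
) -> np.ndarray:
    """Same values as :func:`_emission_block`, written into preallocated
    buffers to keep the inner recursion loop allocation-light."""
    np.equal(hap_row[:, None], recip_alleles[None, :], out=eq)
    if use_speidel:
        out[:] = np.where(recip_alleles[None, :] == 1, mu, 1.0)
    else:
        out.fill(mu)
    np.copyto(out, 1.0 - mu, where=eq)
    return out


def emission_vector(
    cache: HaplotypeCache,
    variant: int,
    recipient: int,
    mu_at_l: float,
    use_speidel: bool = False,
) -> np.ndarray:
    """Length-N emission vector ``theta^l_{. i}`` for one recipient.

    The entry at ``j == recipient`` is returned like any other but is
    meaningless under the model (a recipient never copies itself); callers
    must mask it.
    """
    if not 0 <= recipient < cache.num_haps:
        raise IndexError(f"recipient {recipient} out of range [0, {cache.num_haps})")
    row = cache.variant_row(variant).astype(np.int64)
    theta = _emission_block(
        row, row[np.asarray([recipient])], mu_at_l, use_speidel
    )
    return theta[:, 0]


# --- shared checks ---------------------------------------------------------

def _check_pars_cache(pars: ModelParameters, cache: HaplotypeCache) -> None:
    if pars.num_haps != cache.num_haps:
        raise ValueError(
            f"parameter set is for N={pars.num_haps} haplotypes but the cache "
            f"holds N={cache.num_haps}"
        )
    if pars.num_variants != cache.num_variants:
        raise ValueError(
            f"parameter set is for L={pars.num_variants} variants but the cache "
            f"holds L={cache.num_variants}"
        )


def _check_hash(table, pars: ModelParameters) -> None:
    if table.pars_hash is not None and table.pars_hash != pars.content_hash:
        raise ValueError(
            "parameter hash mismatch: parameter sets must be fixed for all "
            "steps of a given forward or backward computation"
        )


def _mask_diagonal(mat: np.ndarray, recipients: np.ndarray) -> None:
    mat[recipients, np.arange(recipients.size)] = 0.0


def _chunks(n_cols: int, workers: int) -> list[np.ndarray]:
    workers = max(1, min(workers, n_cols))
    return np.array_split(np.arange(n_cols), workers)


# --- forward ---------------------------------------------------------------

def initialise_forward(
    table: ForwardTable, pars: ModelParameters, cache: HaplotypeCache
) -> ForwardTable:
    """Set the table to variant 0: ``alpha^1 = theta^1 * Pi`` columnwise."""
    _check_pars_cache(pars, cache)
    recips = table.recipients
    row = cache.variant_row(0).astype(np.int64)
    theta = _emission_block(row, row[recips], pars.mu_at(0), pars.use_speidel)
    picol = pars.pi_columns(recips)
    alpha = theta * picol
    _mask_diagonal(alpha, recips)
    table.alpha = alpha
    table.alpha_f = _colsums(alpha)
    table.at_variant = 0
    table.pars_hash = pars.content_hash
    return table


def _propagate_forward_block(
    alpha: np.ndarray,
    recips: np.ndarray,
    pars: ModelParameters,
    cache: HaplotypeCache,
    start: int,
    target: int,
    picol: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    rho = pars.rho
    alpha_f = _colsums(alpha)
    prior_term = np.empty_like(alpha)
    theta = np.empty_like(alpha)
    eq = np.empty(alpha.shape, dtype=bool)
    for ell in range(start + 1, target + 1):
        s = _colsums(alpha)  # previous-state column sums
        row = cache.variant_row(ell).astype(np.int64)
        _emission_into(theta, eq, row, row[recips], pars.mu_at(ell),
                       pars.use_speidel)
        r = rho[ell - 1]
        # in place, in the fixed order: normalise, decay, add prior, emit
        np.divide(alpha, s, out=alpha)
        alpha *= 1.0 - r
        np.multiply(picol, r, out=prior_term)
        alpha += prior_term
        alpha *= theta
        _mask_diagonal(alpha, recips)
        alpha_f = _colsums(alpha)
    return alpha, alpha_f


def forward(
    table: ForwardTable,
    pars: ModelParameters,
    cache: HaplotypeCache,
    target_variant: int,
    workers: int = 1,
) -> ForwardTable:
    """Propagate the table up to ``target_variant`` (0-based).

    Each recipient column is propagated independently all the way to the
    target.  An uninitialised table is auto-initialised first (logged).
    Forward tables cannot move backwards.
    """
    _check_pars_cache(pars, cache)
    if not 0 <= target_variant < cache.num_variants:
        raise IndexError(
            f"target variant {target_variant} out of range [0, {cache.num_variants})"
        )
    _check_hash(table, pars)
    if not table.initialised:
        logger.info("auto-initialising forward table at variant 0")
        initialise_forward(table, pars, cache)
    if target_variant < table.at_variant:
        raise ValueError(
            f"forward tables cannot move backwards (at variant "
            f"{table.at_variant}, target {target_variant})"
        )
    if target_variant == table.at_variant:
        return table
    recips = table.recipients
    picol = pars.pi_columns(recips)
    chunks = _chunks(recips.size, workers)
    if len(chunks) == 1:
        table.alpha, table.alpha_f = _propagate_forward_block(
            table.alpha, recips, pars, cache, table.at_variant, target_variant, picol
        )
    else:
        def run(cols):
            return _propagate_forward_block(
                np.ascontiguousarray(table.alpha[:, cols]),
                recips[cols],
                pars,
                cache,
                table.at_variant,
                target_variant,
                np.ascontiguousarray(picol[:, cols]),
            )

        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            results = list(pool.map(run, chunks))
        alpha = np.empty_like(table.alpha)
        alpha_f = np.empty_like(table.alpha_f)
        for cols, (a, f) in zip(chunks, results):
            alpha[:, cols] = a
            alpha_f[cols] = f
        table.alpha, table.alpha_f = alpha, alpha_f
    table.at_variant = target_variant
    return table


# --- backward --------------------------------------------------------------

def initialise_backward(
    table: BackwardTable, pars: ModelParameters, cache: HaplotypeCache
) -> BackwardTable:
    """Set the table to the last variant: ``beta^L = 1`` (diagonal masked),
    unit scaling sums, standard probability space."""
    _check_pars_cache(pars, cache)
    recips = table.recipients
    beta = np.ones((table.num_haps, recips.size))
    _mask_diagonal(beta, recips)
    table.beta = beta
    table.beta_g = np.ones(recips.size)
    table.at_variant = cache.num_variants - 1
    table.pars_hash = pars.content_hash
    table.beta_theta = False
    return table


def _propagate_backward_block(
    beta: np.ndarray,
    beta_g: np.ndarray,
    beta_theta: bool,
    recips: np.ndarray,
    pars: ModelParameters,
    cache: HaplotypeCache,
    start: int,
    target: int,
    picol: np.ndarray,
    return_rescaled: bool,
) -> tuple[np.ndarray, np.ndarray, bool]:
    rho = pars.rho
    weighted = np.empty_like(beta)
    theta = np.empty_like(beta)
    eq = np.empty(beta.shape, dtype=bool)
    for ell in range(start - 1, target - 1, -1):
        if beta_theta:
            beta_theta = False  # stored matrix already carries theta^{l+1}
        else:
            row = cache.variant_row(ell + 1).astype(np.int64)
            _emission_into(theta, eq, row, row[recips], pars.mu_at(ell + 1),
                           pars.use_speidel)
            np.multiply(beta, theta, out=beta)
        np.multiply(beta, picol, out=weighted)
        g = _colsums(weighted)
        r = rho[ell]
        # in place, in the fixed order: normalise, decay, add switch mass
        np.divide(beta, g, out=beta)
        beta *= 1.0 - r
        beta += r
        _mask_diagonal(beta, recips)
        beta_g = g
    if return_rescaled != beta_theta:
        row = cache.variant_row(target).astype(np.int64)
        theta_here = _emission_block(
            row, row[recips], pars.mu_at(target), pars.use_speidel
        )
        beta = beta * theta_here if return_rescaled else beta / theta_here
        _mask_diagonal(beta, recips)
        beta_theta = return_rescaled
    return beta, beta_g, beta_theta


def backward(
    table: BackwardTable,
    pars: ModelParameters,
    cache: HaplotypeCache,
    target_variant: int,
    return_rescaled: bool = False,
    workers: int = 1,
) -> BackwardTable:
    """Propagate the table down to ``target_variant`` (0-based).

    With ``return_rescaled`` the stored matrix additionally carries the
    emission factor of the target variant (``beta_theta=True``); a later
    call first completes the pending step from that rescaled space.
    Backward tables cannot move forwards.
    """
    _check_pars_cache(pars, cache)
    if not 0 <= target_variant < cache.num_variants:
        raise IndexError(
            f"target variant {target_variant} out of range [0, {cache.num_variants})"
        )
    _check_hash(table, pars)
    if not table.initialised:
        logger.info(
            "auto-initialising backward table at variant %d", cache.num_variants - 1
        )
        initialise_backward(table, pars, cache)
    if target_variant > table.at_variant:
        raise ValueError(
            f"backward tables cannot move forwards (at variant "
            f"{table.at_variant}, target {target_variant})"
        )
    if target_variant == table.at_variant and return_rescaled == table.beta_theta:
        return table
    recips = table.recipients
    picol = pars.pi_columns(recips)
    chunks = _chunks(recips.size, workers)
    if len(chunks) == 1:
        table.beta, table.beta_g, table.beta_theta = _propagate_backward_block(
            table.beta,
            table.beta_g,
            table.beta_theta,
            recips,
            pars,
            cache,
            table.at_variant,
            target_variant,
            picol,
            return_rescaled,
        )
    else:
        def run(cols):
            return _propagate_backward_block(
                np.ascontiguousarray(table.beta[:, cols]),
                table.beta_g[cols].copy(),
                table.beta_theta,
                recips[cols],
                pars,
                cache,
                table.at_variant,
                target_variant,
                np.ascontiguousarray(picol[:, cols]),
                return_rescaled,
            )

        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            results = list(pool.map(run, chunks))
        beta = np.empty_like(table.beta)
        beta_g = np.empty_like(table.beta_g)
        flag = results[0][2]
        for cols, (b, g, _) in zip(chunks, results):
            beta[:, cols] = b
            beta_g[cols] = g
        table.beta, table.beta_g, table.beta_theta = beta, beta_g, flag
    table.at_variant = target_variant
    return table


# --- utilities -------------------------------------------------------------

def copy_table(table):
    """Deep, independent copy of a forward or backward table."""
    if isinstance(table, ForwardTable):
        return ForwardTable(
            num_haps=table.num_haps,
            from_recipient=table.from_recipient,
            to_recipient=table.to_recipient,
            alpha=None if table.alpha is None else table.alpha.copy(),
            alpha_f=None if table.alpha_f is None else table.alpha_f.copy(),
            at_variant=table.at_variant,
            pars_hash=table.pars_hash,
        )
    if isinstance(table, BackwardTable):
        return BackwardTable(
            num_haps=table.num_haps,
            from_recipient=table.from_recipient,
            to_recipient=table.to_recipient,
            beta=None if table.beta is None else table.beta.copy(),
            beta_g=None if table.beta_g is None else table.beta_g.copy(),
            at_variant=table.at_variant,
            pars_hash=table.pars_hash,
            beta_theta=table.beta_theta,
        )
    raise TypeError(f"not a table: {type(table)}")


def save_table(table, path) -> None:
    """Checkpoint a table to HDF5 (datasets ``alpha``/``beta`` and scaling
    sums, plus slice/position metadata as attributes)."""
    is_fwd = isinstance(table, ForwardTable)
    if not isinstance(table, (ForwardTable, BackwardTable)):
        raise TypeError(f"not a table: {type(table)}")
    if not table.initialised:
        raise ValueError("cannot checkpoint an uninitialised table")
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "forward" if is_fwd else "backward"
        f.attrs["num_haps"] = table.num_haps
        f.attrs["from_recipient"] = table.from_recipient
        f.attrs["to_recipient"] = table.to_recipient
        f.attrs["at_variant"] = table.at_variant
        f.attrs["pars_hash"] = table.pars_hash
        if is_fwd:
            f.create_dataset("alpha", data=table.alpha)
            f.create_dataset("alpha_f", data=table.alpha_f)
        else:
            f.create_dataset("beta", data=table.beta)
            f.create_dataset("beta_g", data=table.beta_g)
            f.attrs["beta_theta"] = table.beta_theta


def load_table(path):
    """Restore a checkpointed table written by :func:`save_table`."""
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        common = dict(
            num_haps=int(f.attrs["num_haps"]),
            from_recipient=int(f.attrs["from_recipient"]),
            to_recipient=int(f.attrs["to_recipient"]),
            at_variant=int(f.attrs["at_variant"]),
            pars_hash=str(f.attrs["pars_hash"]),
        )
        if kind == "forward":
            return ForwardTable(
                alpha=f["alpha"][...], alpha_f=f["alpha_f"][...], **common
            )
        return BackwardTable(
            beta=f["beta"][...],
            beta_g=f["beta_g"][...],
            beta_theta=bool(f.attrs["beta_theta"]),
            **common,
        )
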