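"""Weight construction and sparse rewiring.

Unconstrained networks use the Gaussian initialization W ~ (w0/sqrt(n_in)) N(0,1)
where n_in is the number of afferents (columns).  Sign-constrained (Dale's law)
networks draw a sign kappa_i per presynaptic neuron, sample |N(0,1)| magnitudes,
balance each row to zero sum, and rescale by the spectral radius before applying
w0.  DEEP R keeps the number of active connections and every connection's sign
fixed throughout training by disconnecting weights that would flip sign and
reconnecting the same number of synapses at uniformly random free coordinates.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightSet",
    "RewiringConfig",
    "init_unconstrained",
    "init_dale",
    "sparsify",
    "deepr_step",
]

#: voltage-equivalent weight scale, w0 = 1 Volt / R_m * delta_t, in mV units
W0_DEFAULT = 1000.0


@dataclass
class WeightSet:
    """Input, recurrent and readout weights with delays, signs and masks.

    Masked-out entries are kept at exactly 0; in Dale mode every nonzero
    entry of column i of w_rec / w_out carries ``sign[i]``.  Delays are
    integer ms, >= 1; ``None`` means a uniform delay of 1.
    """

    w_in: np.ndarray
    w_rec: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray | None = None
    d_in: np.ndarray | int | None = None
    d_rec: np.ndarray | int | None = None
    sign: np.ndarray | None = None
    mask_in: np.ndarray | None = None
    mask_rec: np.ndarray | None = None
    mask_out: np.ndarray | None = None
    w0: float = W0_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        np.fill_diagonal(self.w_rec, 0.0)
        if self.b_out is None:
            self.b_out = np.zeros(self.w_out.shape[0])
        for w, m in ((self.w_in, self.mask_in), (self.w_rec, self.mask_rec),
                     (self.w_out, self.mask_out)):
            if m is not None:
                w *= m

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    def delay_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        d_in = (np.ones_like(self.w_in, dtype=np.int64) if self.d_in is None
                else np.broadcast_to(np.asarray(self.d_in, dtype=np.int64), self.w_in.shape))
        d_rec = (np.ones_like(self.w_rec, dtype=np.int64) if self.d_rec is None
                 else np.broadcast_to(np.asarray(self.d_rec, dtype=np.int64), self.w_rec.shape))
        if d_in.min() < 1 or d_rec.min() < 1:
            raise ValueError("synaptic delays must be >= 1 step")
        return d_in, d_rec

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.w_in.copy(), self.w_rec.copy(), self.w_out.copy(),
            None if self.b_out is None else self.b_out.copy(),
            _copy_opt(self.d_in), _copy_opt(self.d_rec), _copy_opt(self.sign),
            _copy_opt(self.mask_in), _copy_opt(self.mask_rec), _copy_opt(self.mask_out),
            self.w0, dict(self.meta),
        )

    def state_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for arr in (self.w_in, self.w_rec, self.w_out, self.b_out):
            h.update(np.ascontiguousarray(arr).tobytes())
        for arr in (self.mask_in, self.mask_rec, self.mask_out, self.sign):
            if arr is not None:
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- serialization ----------------------------------------------------
    def save(self, h5group) -> None:
        for name in ("w_in", "w_rec", "w_out", "b_out"):
            h5group.create_dataset(name, data=getattr(self, name))
        for name in ("d_in", "d_rec", "sign", "mask_in", "mask_rec", "mask_out"):
            val = getattr(self, name)
            if val is not None:
                h5group.create_dataset(name, data=np.asarray(val))
        h5group.attrs["w0"] = self.w0
        h5group.attrs["meta"] = json.dumps(self.meta)

    @staticmethod
    def load(h5group) -> "WeightSet":
        kw = {name: h5group[name][()] for name in h5group.keys()}
        return WeightSet(w0=float(h5group.attrs.get("w0", W0_DEFAULT)),
                         meta=json.loads(h5group.attrs.get("meta", "{}")), **kw)

    def summary(self) -> dict:
        out = {
            "n": self.n, "n_in": self.n_in, "n_out": self.w_out.shape[0],
            "w0": self.w0,
            "rec_connectivity": float(np.mean(self.mask_rec)) if self.mask_rec is not None
            else float(np.mean(self.w_rec != 0)),
        }
        if self.w_rec.shape[0] == self.w_rec.shape[1]:
            out["rec_spectral_radius"] = float(np.max(np.abs(np.linalg.eigvals(self.w_rec))))
        return out


def _copy_opt(x):
    return None if x is None or np.isscalar(x) else np.asarray(x).copy()


def init_unconstrained(n_rows: int, n_cols: int, w0: float = W0_DEFAULT,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Gaussian init with std w0/sqrt(n_in); n_in = number of afferents (columns)."""
    if n_cols < 1:
        raise ValueError("need at least one afferent")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.standard_normal((n_rows, n_cols)) * (w0 / np.sqrt(n_cols))


def init_dale(n_rows: int, n_cols: int, frac_excitatory: float = 0.8,
              w0: float = W0_DEFAULT, seed: int | np.random.Generator = 0,
              sign: np.ndarray | None = None,
              balance: bool = True, spectral: bool = True,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Sign-constrained init; returns (weights, per-column sign kappa).

    Steps: (1) kappa_i ~ Bernoulli(frac_excitatory) over {+1,-1} unless an
    explicit ``sign`` vector is given; (2) entries kappa_i * |N(0,1)|;
    (3) a per-row constant added to one sign class so each row sums to zero
    (sign-safe; skipped with a warning when a row has only one sign);
    (4) division by the spectral radius (non-square matrices are cut
    uniformly from a larger square one); (5) scaling by w0.  The
    ``balance`` / ``spectral`` hooks disable steps (3)/(4) for testing.
    """
    if sign is None and not 0 < frac_excitatory < 1:
        raise ValueError("frac_excitatory must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_sq = max(n_rows, n_cols)
    if sign is not None:
        sign = np.asarray(sign)
        sign_sq = np.concatenate([sign, np.where(
            rng.random(n_sq - n_cols) < frac_excitatory, 1, -1)]) if n_sq > n_cols else sign
    else:
        sign_sq = np.where(rng.random(n_sq) < frac_excitatory, 1, -1)
    w = np.abs(rng.standard_normal((n_sq, n_sq))) * sign_sq[None, :]

    if balance:
        w = _zero_row_sums(w, sign_sq)
    if spectral:
        radius = np.max(np.abs(np.linalg.eigvals(w)))
        if radius > 0:
            w = w / radius
    if n_sq > n_rows:
        w = w[np.sort(rng.choice(n_sq, n_rows, replace=False))]
    if n_sq > n_cols:
        cols = np.sort(rng.choice(n_sq, n_cols, replace=False))
        w, sign_sq = w[:, cols], sign_sq[cols]
    return w * w0, sign_sq.astype(np.int64)


def _zero_row_sums(w: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Add a per-row constant to one sign class so every row sums to zero.

    The constant is applied to the class whose magnitudes must grow, so no
    entry ever crosses zero and Dale signs are preserved exactly.
    """
    w = w.copy()
    exc, inh = sign > 0, sign < 0
    n_exc, n_inh = int(exc.sum()), int(inh.sum())
    if n_exc == 0 or n_inh == 0:
        warnings.warn("row balancing skipped: all afferents share one sign")
        return w
    s = w.sum(axis=1)
    pos = s > 0
    w[np.ix_(pos, inh)] += (-s[pos] / n_inh)[:, None]
    w[np.ix_(~pos, exc)] += (-s[~pos] / n_exc)[:, None]
    return w


def sparsify(weights: np.ndarray, connectivity: float,
             seed: int | np.random.Generator = 0,
             exclude_diagonal: bool = False) -> np.ndarray:
    """Binary mask with exactly round(connectivity * n_entries) ones.

    For recurrent matrices pass ``exclude_diagonal=True``: self-connections
    are never eligible and the entry count is n*(n-1).
    """
    if not 0 < connectivity <= 1:
        raise ValueError("connectivity must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nr, nc = weights.shape
    eligible = np.ones((nr, nc), dtype=bool)
    if exclude_diagonal:
        np.fill_diagonal(eligible, False)
    flat = np.flatnonzero(eligible)
    k = int(round(connectivity * flat.size))
    chosen = rng.choice(flat, size=k, replace=False)
    mask = np.zeros(nr * nc, dtype=np.float64)
    mask[chosen] = 1.0
    return mask.reshape(nr, nc)


@dataclass
class RewiringConfig:
    """DEEP R parameters (temperature 0 => no stochastic exploration noise)."""

    connectivity: float = 0.2
    l1: float = 0.01
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.connectivity <= 1:
            raise ValueError("connectivity must be in (0, 1]")
        if self.l1 < 0 or self.temperature < 0:
            raise ValueError("l1 and temperature must be non-negative")


def deepr_step(weights: np.ndarray, mask: np.ndarray, sign: np.ndarray,
               grads: np.ndarray, lr: float, cfg: RewiringConfig,
               seed: int | np.random.Generator = 0,
               exclude_diagonal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """One DEEP R update; returns (new weights, new mask).

    Active weights take a gradient step with constant L1 shrinkage
    ``lr * l1 * sign(w)`` (plus sqrt(2*lr*T) Gaussian noise if temperature
    T > 0).  Any active weight pushed against its owner's sign is
    disconnected; for each disconnection one free coordinate is activated at
    magnitude 0 with the owner's sign, so the active count is conserved
    exactly and no sign ever changes.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    active = mask > 0
    col_sign = np.broadcast_to(np.asarray(sign)[None, :], weights.shape)
    w = weights.copy()
    step = -lr * grads - lr * cfg.l1 * col_sign
    if cfg.temperature > 0:
        step = step + np.sqrt(2.0 * lr * cfg.temperature) * rng.standard_normal(w.shape)
    w[active] += step[active]

    flipped = active & (col_sign * w < 0)
    n_flip = int(flipped.sum())
    w[flipped] = 0.0
    new_mask = mask.copy()
    new_mask[flipped] = 0.0
    if n_flip:
        eligible = new_mask == 0
        if exclude_diagonal:
            np.fill_diagonal(eligible, False)
        free = np.flatnonzero(eligible)
        if free.size < n_flip:
            logger.warning("DEEP R: only %d free coordinates for %d reconnections",
                           free.size, n_flip)
            n_flip = free.size
        chosen = rng.choice(free, size=n_flip, replace=False)
        new_mask.flat[chosen] = 1.0
        w.flat[chosen] = 0.0  # reconnect at magnitude 0 with the owner's sign
    w *= new_mask
    return w, new_mask
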