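"""Frequency-domain directed connectivity (iPDC) and the group 5-way tensor.

From a fitted time-varying MVAR model, the Fourier-transformed coefficient
matrix

    Abar(f, t) = I − sum_{k=1..p} A_k(t) e^{−i 2π f k / fs}

is column-normalized into the information partial directed coherence (iPDC),
a Granger-causal measure of the directed influence of channel j onto i:

    iPDC_ij(f, t) = |Abar_ij(f, t)| σ_ii^{−1/2}
                    / sqrt( abar_j(f, t)^H Σw^{−1} abar_j(f, t) )

where ``abar_j`` is column j of Abar and ``σ_ii`` the residual variance of
the target channel.  With diagonal unit residual covariance this reduces to
the generalized PDC, whose squared values sum to one over targets for each
(source, f, t).  The normalization is applied independently at every time and
frequency point, which makes iPDC insensitive to 1/f power gradients.

Per-animal magnitudes are then unfolded to a nonnegative 5-way array —
source layer × target layer × time × frequency × between-area connection —
and averaged over animals (within-area blocks are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .stok import TvMVARModel

__all__ = [
    "ConnectivityTensor",
    "spectral_coeffs",
    "ipdc",
    "build_group_tensor",
    "morlet_psd",
]

DEFAULT_FREQS = np.arange(1.0, 101.0)  # 1…100 Hz, 1-Hz resolution


@dataclass
class ConnectivityTensor:
    """Nonnegative directed-connectivity values on labeled axes.

    Two layouts are used:

    * per-animal, before unfolding: ``values`` has shape (n_ch, n_ch, T, F)
      with ``values[i, j]`` the influence of channel j (source) onto i
      (target); ``channels`` carries the (area, layer) metadata.
    * group, unfolded: shape (n_layers, n_layers, T, F, n_connections) on axes
      source layer × target layer × time × frequency × connection, where
      ``connections`` lists ordered between-area pairs (source_area,
      target_area).
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    layers: list = field(default_factory=list)
    connections: list = field(default_factory=list)
    channels: pd.DataFrame | None = None
    condition: str = ""
    animals: list = field(default_factory=list)

    @property
    def unfolded(self) -> bool:
        return self.values.ndim == 5


def spectral_coeffs(model: TvMVARModel, freqs: Sequence[float],
                    dtype=np.complex128) -> np.ndarray:
    """Fourier-transformed tvMVAR coefficients ``Abar(t, f)``.

    Returns
    -------
    ndarray, shape (n_times, n_freqs, n, n), complex.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs > model.fs / 2.0):
        raise ValueError("frequencies above Nyquist")
    p, n = model.p, model.n_channels
    E = np.exp(-2j * np.pi * np.outer(np.arange(1, p + 1), freqs) / model.fs)
    E = E.astype(dtype)
    A = model.A.astype(np.float32 if dtype == np.complex64 else np.float64)
    # (T, p, n, n) x (p, F) -> (T, F, n, n)
    Abar = -np.tensordot(A, E, axes=(1, 0)).transpose(0, 3, 1, 2)
    idx = np.arange(n)
    Abar[:, :, idx, idx] += 1.0
    return Abar


def ipdc(model: TvMVARModel, freqs: Sequence[float] = DEFAULT_FREQS,
         channels: pd.DataFrame | None = None,
         chunk: int = 32, dtype=np.float64,
         condition: str = "", animal: str = "") -> ConnectivityTensor:
    """Information partial directed coherence of a tvMVAR model.

    Returns a per-animal :class:`ConnectivityTensor` with values of shape
    (n_targets, n_sources, n_times, n_freqs); absolute values are stored.

    Raises
    ------
    ValueError
        If the residual covariance is singular.
    """
    freqs = np.asarray(freqs, dtype=float)
    sigma = model.sigma
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or logdet < -300:
        raise ValueError("singular residual covariance")
    siginv = np.linalg.inv(sigma)
    sii = np.sqrt(np.diag(sigma))
    T, n = model.A.shape[0], model.n_channels
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    out = np.empty((n, n, T, len(freqs)), dtype=dtype)
    for t0 in range(0, T, chunk):
        sub = TvMVARModel(A=model.A[t0:t0 + chunk], sigma=sigma, p=model.p,
                          c=model.c, fs=model.fs, times=model.times[t0:t0 + chunk])
        Abar = spectral_coeffs(sub, freqs, dtype=cdtype)  # (tc, F, n, n)
        num = np.abs(Abar)  # |Abar_ij|
        # denominator: sqrt(abar_j^H Siginv abar_j) for each column j
        den = np.sqrt(np.maximum(np.real(
            np.einsum("tfij,ik,tfkj->tfj", Abar.conj(),
                      siginv.astype(cdtype), Abar, optimize=True)), 0.0))
        vals = num / (sii[None, None, :, None] * den[:, :, None, :])
        out[:, :, t0:t0 + chunk, :] = vals.transpose(2, 3, 0, 1)
    return ConnectivityTensor(values=out, times=model.times, freqs=freqs,
                              channels=channels, condition=condition,
                              animals=[animal] if animal else [])


def _unfold_animal(tensor: ConnectivityTensor, layers: list,
                   connections: list) -> tuple[np.ndarray, np.ndarray]:
    """Unfold one animal's (n_ch, n_ch, T, F) tensor to 5-way layout.

    Returns (values, mask) where mask marks connections present for this
    animal (both areas recorded).
    """
    meta = tensor.channels
    if meta is None:
        raise ValueError("per-animal tensor lacks channel metadata")
    n_l = len(layers)
    T, F = tensor.values.shape[2], tensor.values.shape[3]
    out = np.zeros((n_l, n_l, T, F, len(connections)), dtype=tensor.values.dtype)
    mask = np.zeros(len(connections), dtype=bool)
    index = {(row.area, row.layer): i for i, row in enumerate(meta.itertuples())}
    areas = set(meta["area"])
    for ci, (src_area, tgt_area) in enumerate(connections):
        if src_area not in areas or tgt_area not in areas:
            continue
        ok = True
        for sl in layers:
            for tl in layers:
                si = index.get((src_area, sl))
                ti = index.get((tgt_area, tl))
                if si is None or ti is None:
                    ok = False
                    continue
                out[layers.index(sl), layers.index(tl), :, :, ci] = \
                    tensor.values[ti, si]
        if not ok:
            out[:, :, :, :, ci] = 0.0
        mask[ci] = ok
    return out, mask


def build_group_tensor(per_animal: Sequence[ConnectivityTensor],
                       layers: Sequence[str] | None = None,
                       areas: Sequence[str] | None = None) -> ConnectivityTensor:
    """Average per-animal iPDC tensors into the unfolded group tensor.

    Within-area blocks are dropped; the remaining values are reorganized to
    source layer × target layer × time × frequency × between-area connection
    and averaged element-wise over the animals that recorded both areas of a
    connection.

    Raises
    ------
    ValueError
        If some connection is covered by no animal (the pair is named).
    """
    if not per_animal:
        raise ValueError("need at least one animal")
    first = per_animal[0]
    if areas is None:
        areas = sorted(set().union(*[set(t.channels["area"]) for t in per_animal]),
                       key=lambda a: _AREA_ORDER.get(a, 99))
    if layers is None:
        layers = sorted(set(first.channels["layer"]))
    layers = list(layers)
    connections = [(a, b) for a in areas for b in areas if a != b]
    acc = None
    counts = np.zeros(len(connections))
    for t in per_animal:
        vals, mask = _unfold_animal(t, layers, connections)
        if acc is None:
            acc = np.zeros_like(vals, dtype=np.float64)
        acc += vals
        counts += mask.astype(float)
    if np.any(counts == 0):
        missing = [connections[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"no animal covers connections: {missing}")
    acc /= counts[None, None, None, None, :]
    animals = [a for t in per_animal for a in t.animals]
    return ConnectivityTensor(values=acc, times=first.times, freqs=first.freqs,
                              layers=layers, connections=connections,
                              condition=first.condition, animals=animals)


#: Anatomical hierarchy order used for a stable connection-axis ordering.
_AREA_ORDER = {"V1": 0, "LM": 1, "RL": 2, "AL": 3, "PM": 4, "AM": 5}


def _morlet_power(x: np.ndarray, fs: float, freqs: np.ndarray,
                  n_cycles: float, pad_factor: int) -> np.ndarray:
    """Complex-Morlet wavelet power of x (..., T) -> (..., F, T)."""
    T = x.shape[-1]
    # reflect-pad to suppress edge artifacts, then pad to a power of two
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(T, T)], mode="reflect")
    n_fft = int(2 ** np.ceil(np.log2(xp.shape[-1] * (1 + pad_factor))))
    Xf = np.fft.fft(xp, n=n_fft, axis=-1)
    fax = np.fft.fftfreq(n_fft, d=1.0 / fs)
    power = np.empty(x.shape[:-1] + (len(freqs), T))
    for fi, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        # frequency-domain Gaussian centered on f (analytic wavelet)
        Wf = np.exp(-0.5 * ((fax - f) * 2.0 * np.pi * sigma_t) ** 2)
        Wf[fax < 0] = 0.0
        conv = np.fft.ifft(Xf * Wf, axis=-1)[..., T:2 * T]
        power[..., fi, :] = np.abs(conv) ** 2
    return power


def morlet_psd(epochs: EpochSet,
               freqs: Sequence[float] = DEFAULT_FREQS,
               n_cycles: float = 6.0,
               pad_factor: int = 1,
               baseline: tuple[float, float] | None = (-0.3, -0.05),
               percent_change: bool = True) -> np.ndarray:
    """Morlet-wavelet power, optionally as percent change from baseline.

    Power is averaged over trials; with ``percent_change`` the result is
    ``100 · (P − P̄_base) / P̄_base`` per frequency and channel, where the
    baseline is the pre-stimulus window mean (default −300…−50 ms, avoiding
    smearing of the fast onset response into the baseline).

    Returns
    -------
    ndarray, shape (n_times, n_freqs, n_channels).
    """
    freqs = np.asarray(freqs, dtype=float)
    power = _morlet_power(epochs.signals, epochs.fs, freqs,
                          n_cycles, pad_factor)  # (N, n, F, T)
    power = power.mean(axis=0)  # (n, F, T)
    power = power.transpose(2, 1, 0)  # (T, F, n)
    if not percent_change:
        return power
    t0, t1 = baseline
    sel = (epochs.times >= t0) & (epochs.times <= t1)
    if not np.any(sel):
        raise ValueError("baseline window outside epoch")
    base = power[sel].mean(axis=0, keepdims=True)
    return 100.0 * (power - base) / base
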