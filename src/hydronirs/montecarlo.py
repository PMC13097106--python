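"""Seeded white Monte Carlo photon transport for semi-infinite reflectance.

A single absorption-free ("white") simulation at unit reduced scattering
(musp = 1 mm^-1, isotropic phase function) records, for every photon packet
leaving the surface, the exit radius and total path length into a 2-D
histogram. Reflectance at arbitrary (mua, musp, rho, modulation frequency)
then follows from similarity scaling:

* path lengths and radii scale as 1/musp,
* absorption attenuates each path by exp(-mua * L),
* modulation adds a phase factor exp(-i * omega * n * L / c).

The refractive-index mismatch at the boundary is handled with unpolarized
Fresnel reflection and weight splitting (the transmitted fraction is scored,
the reflected fraction continues). Photons are launched normally into the
medium at the origin; specular loss at entry is not modelled (measured
amplitudes are relative and calibrated downstream).

Truncation: paths longer than ``l_max`` (default 2500 mm at musp = 1) and
photons wandering beyond ``r_kill`` are dropped; both limits are far into
the exponentially attenuated tail for the optical-property range covered by
the default look-up-table grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import SPEED_OF_LIGHT_MM_PER_NS, _fresnel_unpolarized

__all__ = ["WhiteMonteCarlo"]


def _make_kernel():
    """Compile the per-photon transport loop (numba, single-threaded)."""
    import numba

    @numba.njit(cache=True)
    def fresnel(cos_i, n_rel):
        if cos_i > 1.0:
            cos_i = 1.0
        sin_i = np.sqrt(1.0 - cos_i * cos_i)
        sin_t = n_rel * sin_i
        if sin_t >= 1.0:
            return 1.0
        cos_t = np.sqrt(1.0 - sin_t * sin_t)
        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
        return 0.5 * (rs * rs + rp * rp)

    @numba.njit(cache=True)
    def trace(
        n_photons,
        seed,
        n_medium,
        log_r_min,
        dlog_r,
        n_r_bins,
        r_lo,
        r_hi,
        log_l_min,
        dlog_l,
        n_l_bins,
        l_lo,
        l_hi,
        l_max,
        r_kill,
        w_min,
    ):
        np.random.seed(seed)
        w_hist = np.zeros((n_r_bins, n_l_bins))
        wl_hist = np.zeros((n_r_bins, n_l_bins))
        for _ in range(n_photons):
            x = 0.0
            y = 0.0
            z = 0.0
            ux = 0.0
            uy = 0.0
            uz = 1.0
            w = 1.0
            path = 0.0
            while True:
                s = -np.log(np.random.random())
                if uz < 0.0 and z + uz * s < 0.0:
                    s_b = -z / uz
                    xb = x + ux * s_b
                    yb = y + uy * s_b
                    lb = path + s_b
                    refl = fresnel(-uz, n_medium)
                    if refl < 1.0:
                        r_exit = np.sqrt(xb * xb + yb * yb)
                        if r_lo <= r_exit < r_hi and l_lo <= lb < l_hi:
                            ri = int((np.log(r_exit) - log_r_min) / dlog_r)
                            li = int((np.log(lb) - log_l_min) / dlog_l)
                            wt = w * (1.0 - refl)
                            w_hist[ri, li] += wt
                            wl_hist[ri, li] += wt * lb
                    w *= refl
                    s_rem = s - s_b
                    x = xb + ux * s_rem
                    y = yb + uy * s_rem
                    z = -uz * s_rem
                    uz = -uz
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                path += s
                if path >= l_max or x * x + y * y >= r_kill * r_kill:
                    break
                if w < w_min:
                    if np.random.random() < 0.1:
                        w *= 10.0
                    else:
                        break
                cos_t = 2.0 * np.random.random() - 1.0
                sin_t = np.sqrt(1.0 - cos_t * cos_t)
                phi = 2.0 * np.pi * np.random.random()
                ux = sin_t * np.cos(phi)
                uy = sin_t * np.sin(phi)
                uz = cos_t
        return w_hist, wl_hist

    return trace


_KERNEL = None


@dataclass
class WhiteMonteCarlo:
    """White Monte Carlo engine; ``run()`` once, then evaluate ``reflectance``."""

    n_photons: int = 2_000_000
    seed: int | None = None
    n_medium: float = 1.4
    r_min: float = 3.0  # mm, recording annulus range (at musp = 1)
    r_max: float = 70.0
    n_r_bins: int = 640
    l_max: float = 5000.0  # mm, path truncation (at musp = 1)
    n_l_bins: int = 460
    r_kill: float = 150.0
    batch_size: int = 250_000
    weight_min: float = 1e-3

    _w_hist: np.ndarray | None = field(default=None, repr=False)
    _wl_hist: np.ndarray | None = field(default=None, repr=False)

    # -- geometry of the histograms ---------------------------------------

    @property
    def r_edges(self) -> np.ndarray:
        return np.geomspace(self.r_min, self.r_max, self.n_r_bins + 1)

    @property
    def l_edges(self) -> np.ndarray:
        return np.geomspace(self.r_min, self.l_max, self.n_l_bins + 1)

    # -- transport ---------------------------------------------------------

    def run(self) -> None:
        """Trace all photon packets (seeded, deterministic)."""
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        r_edges = self.r_edges
        l_edges = self.l_edges
        global _KERNEL
        try:
            if _KERNEL is None:
                _KERNEL = _make_kernel()
            w_hist, wl_hist = _KERNEL(
                self.n_photons,
                self.seed % (2**32),
                self.n_medium,
                np.log(r_edges[0]),
                np.log(r_edges[1] / r_edges[0]),
                self.n_r_bins,
                r_edges[0],
                r_edges[-1],
                np.log(l_edges[0]),
                np.log(l_edges[1] / l_edges[0]),
                self.n_l_bins,
                l_edges[0],
                l_edges[-1],
                self.l_max,
                self.r_kill,
                self.weight_min,
            )
        except ImportError:  # pragma: no cover - numba is normally present
            rng = np.random.default_rng(self.seed)
            w_hist = np.zeros((self.n_r_bins, self.n_l_bins))
            wl_hist = np.zeros_like(w_hist)
            remaining = self.n_photons
            while remaining > 0:
                n = min(self.batch_size, remaining)
                remaining -= n
                self._trace_batch(n, rng, r_edges, l_edges, w_hist, wl_hist)

        self._w_hist = w_hist
        self._wl_hist = wl_hist
        self._l_mean = None

    def _trace_batch(self, n, rng, r_edges, l_edges, w_hist, wl_hist) -> None:
        x = np.zeros(n)
        y = np.zeros(n)
        z = np.zeros(n)
        ux = np.zeros(n)
        uy = np.zeros(n)
        uz = np.ones(n)  # launched straight down into the medium
        w = np.ones(n)
        path = np.zeros(n)

        log_r_min = np.log(r_edges[0])
        dlog_r = np.log(r_edges[1] / r_edges[0])
        log_l_min = np.log(l_edges[0])
        dlog_l = np.log(l_edges[1] / l_edges[0])

        while x.size:
            s = rng.exponential(size=x.size)  # mean free path 1/musp = 1 mm
            crossing = (uz < 0) & (z + uz * s < 0)
            if np.any(crossing):
                s_b = np.where(crossing, -z / np.where(uz < 0, uz, -1.0), 0.0)
                xb = x + ux * s_b
                yb = y + uy * s_b
                lb = path + s_b
                cos_i = -uz
                refl = _fresnel_unpolarized(cos_i, self.n_medium)
                t_frac = np.where(crossing, 1.0 - refl, 0.0)
                r_exit = np.hypot(xb, yb)
                score = crossing & (t_frac > 0)
                score &= (r_exit >= r_edges[0]) & (r_exit < r_edges[-1])
                score &= (lb >= l_edges[0]) & (lb < l_edges[-1])
                if np.any(score):
                    ri = ((np.log(r_exit[score]) - log_r_min) / dlog_r).astype(int)
                    li = ((np.log(lb[score]) - log_l_min) / dlog_l).astype(int)
                    wt = w[score] * t_frac[score]
                    flat = ri * self.n_l_bins + li
                    np.add.at(w_hist.ravel(), flat, wt)
                    np.add.at(wl_hist.ravel(), flat, wt * lb[score])
                # reflected fraction continues from the boundary
                w = np.where(crossing, w * refl, w)
                s_rem = np.where(crossing, s - s_b, 0.0)
                x = np.where(crossing, xb + ux * s_rem, x + ux * s)
                y = np.where(crossing, yb + uy * s_rem, y + uy * s)
                z = np.where(crossing, -uz * s_rem, z + uz * s)
                uz = np.where(crossing, -uz, uz)
            else:
                x = x + ux * s
                y = y + uy * s
                z = z + uz * s
            path = path + s

            # isotropic scatter
            cos_t = rng.uniform(-1.0, 1.0, size=x.size)
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=x.size)
            ux = sin_t * np.cos(phi)
            uy = sin_t * np.sin(phi)
            uz = cos_t

            # termination: truncation + Russian roulette
            alive = (path < self.l_max) & (np.hypot(x, y) < self.r_kill)
            low = alive & (w < self.weight_min)
            if np.any(low):
                survive = rng.uniform(size=x.size) < 0.1
                w = np.where(low & survive, w * 10.0, w)
                alive &= ~low | survive
            if not np.all(alive):
                x, y, z = x[alive], y[alive], z[alive]
                ux, uy, uz = ux[alive], uy[alive], uz[alive]
                w, path = w[alive], path[alive]

    # -- evaluation ---------------------------------------------------------

    def reflectance(self, mua, musp, rho: float, frequency_mhz: float) -> np.ndarray:
        """Complex diffuse reflectance per mm^2 per launched photon.

        Broadcasts over ``mua`` and ``musp`` arrays; ``rho`` is the
        source-detector separation in mm.
        """
        if self._w_hist is None:
            raise RuntimeError("call run() first")
        mua = np.atleast_1d(np.asarray(mua, dtype=float))
        musp = np.atleast_1d(np.asarray(musp, dtype=float))
        if mua.shape != musp.shape:
            mua, musp = np.broadcast_arrays(mua, musp)
        out = np.empty(mua.shape, dtype=complex)
        it = np.nditer(mua, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            out[idx] = self._reflectance_one(
                float(mua[idx]), float(musp[idx]), rho, frequency_mhz
            )
        return out

    def _mean_path(self) -> np.ndarray:
        if not hasattr(self, "_l_mean") or self._l_mean is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                self._l_mean = np.where(
                    self._w_hist > 0, self._wl_hist / self._w_hist, 0.0
                )
        return self._l_mean

    def _reflectance_one(
        self, mua: float, musp: float, rho: float, frequency_mhz: float
    ) -> complex:
        m = musp
        r_target = rho * m  # radius in the musp = 1 frame
        mua_scaled = mua / m
        r_edges = self.r_edges
        if not (r_edges[2] < r_target < r_edges[-3]):
            raise ValueError(
                f"scaled radius {r_target:.1f} mm outside recorded range"
            )
        omega = 2.0 * np.pi * frequency_mhz * 1e-3  # rad/ns
        k_time = omega * self.n_medium / SPEED_OF_LIGHT_MM_PER_NS / m  # rad/mm(at musp=1)

        centers = np.sqrt(r_edges[:-1] * r_edges[1:])
        j = int(np.searchsorted(centers, r_target))
        sl = slice(max(0, j - 8), min(centers.size, j + 8))

        # complex attenuation per (r, L) bin using the weighted mean L per bin
        att = np.exp(-(mua_scaled + 1j * k_time) * self._mean_path()[sl])
        bin_sum = (self._w_hist[sl] * att).sum(axis=1)  # per selected r bin

        areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
        density = bin_sum / (areas[sl] * self.n_photons)

        # local log-linear interpolation in r around the target radius
        rc = centers[sl]
        dv = density
        amp = np.abs(dv)
        ok = amp > 0
        if ok.sum() < 3:
            raise ValueError("insufficient Monte Carlo statistics at this radius")
        la = np.polyfit(np.log(rc[ok]), np.log(amp[ok]), 1)
        ph = np.polyfit(np.log(rc[ok]), np.unwrap(np.angle(dv[ok])), 1)
        amplitude = np.exp(np.polyval(la, np.log(r_target)))
        phase = np.polyval(ph, np.log(r_target))
        return m**2 * amplitude * np.exp(1j * phase)
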