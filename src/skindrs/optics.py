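"""Monte Carlo photon transport for a two-separation fiber-optic probe.

Model: a homogeneous semi-infinite turbid medium (z >= 0) probed in contact
by three aligned 400 um fibers (NA 0.22) at 1 mm pitch — one source fiber,
two detector fibers at 1 and 2 mm source-detector separation.  Photons are
launched uniformly over the source face within the NA cone, propagated with
Henyey-Greenstein scattering, and collected when they exit inside a
detector face within the acceptance cone.

Three variance-reduction devices keep the grid builds desk-feasible:

* *white Monte Carlo*: a single zero-absorption run records every detected
  photon's total path length; reflectance at any absorption level follows
  by Beer-Lambert reweighting ``w * exp(-mu_a * L)`` (exact in expectation).
* *azimuthal averaging*: the launch ensemble and medium are rotationally
  symmetric about the source axis, so an escaping flight reaching the
  surface at radius r contributes to a detector face at distance d the
  exact subtended-arc fraction theta*/pi instead of a 0/1 hit.
* *next-event estimation (local estimator)*: at every scattering event the
  kernel tallies the expected detected weight of the next flight — a
  direction drawn uniformly in the upward acceptance cone, weighted by the
  Henyey-Greenstein density, the uncollided escape probability
  ``exp(-mu_t z/|cos|)`` and the detector arc fraction.  Terminal boundary
  exits are then pure escape (never tallied), so nothing is double
  counted.  The detector acceptance cone subtends only ~2% of the exit
  hemisphere, which makes the naive terminal-hit estimator extremely
  sparse; the local estimator harvests information from every event.

Direct (non-white) simulations use the conventional discrete albedo
weighting ``w *= mu_s/mu_t`` at interaction sites, so white-MC rescaling
and direct simulation remain statistically independent routes (different
path ensembles) to the same expectation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ProbeGeometry",
    "MediumOptics",
    "McConfig",
    "McResult",
    "PathDatabase",
    "sample_hg_cosine",
    "simulate_reflectance",
    "build_path_database",
    "rescale_reflectance",
    "rescale_reflectance_with_se",
    "interrogation_depth",
    "diffusion_reflectance",
]

_MAX_TOTAL_PATH_MM = 1000.0  # hard truncation guard for zero-absorption runs
# Unbiased path-length roulette: every _PATH_ROULETTE_STEP_MM of cumulative
# path the photon survives with _PATH_ROULETTE_SURVIVAL (weight boosted
# accordingly).  Tames the heavy first-passage tail of zero-absorption
# random walks; detected-photon weight in that tail is < 1% of R even at
# the lowest grid absorption (0.001 mm^-1), so the variance cost is small.
_PATH_ROULETTE_STEP_MM = 100.0
_PATH_ROULETTE_SURVIVAL = 0.8


@dataclass(frozen=True)
class ProbeGeometry:
    """Three-fiber contact probe: one source, detectors at each SDS.

    NA is specified in air; with the index-matched contact face the
    acceptance cone in tissue has half-angle asin(NA / n_tissue).
    """

    fiber_diameter_mm: float = 0.4
    fiber_na: float = 0.22
    sds_mm: tuple[float, ...] = (1.0, 2.0)
    n_tissue: float = 1.45
    n_ambient: float = 1.45  # matched by default (fused-silica contact probe)

    def __post_init__(self) -> None:
        if self.fiber_diameter_mm <= 0:
            raise ValueError("fiber_diameter must be positive")
        if not 0 < self.fiber_na < self.n_ambient:
            raise ValueError("fiber NA must be in (0, n_ambient)")
        if any(s <= self.fiber_diameter_mm for s in self.sds_mm):
            raise ValueError("every SDS must exceed the fiber diameter")
        if list(self.sds_mm) != sorted(set(self.sds_mm)):
            raise ValueError("sds_mm must be strictly increasing")

    @property
    def fiber_radius_mm(self) -> float:
        return self.fiber_diameter_mm / 2.0

    @property
    def matched(self) -> bool:
        return abs(self.n_tissue - self.n_ambient) < 1e-12

    @property
    def cos_acceptance_tissue(self) -> float:
        """Cosine of the acceptance half-angle evaluated in tissue."""
        return float(np.cos(np.arcsin(self.fiber_na / self.n_tissue)))

    def geometry_hash(self) -> str:
        key = (f"{self.fiber_diameter_mm:.6g}|{self.fiber_na:.6g}|"
               f"{','.join(f'{s:.6g}' for s in self.sds_mm)}|"
               f"{self.n_tissue:.6g}|{self.n_ambient:.6g}")
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class MediumOptics:
    """Homogeneous medium optical properties (mm^-1 coefficients)."""

    mu_a: float
    mu_s_prime: float
    g: float = 0.8

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be > 0")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("g must be in [0, 1)")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g)."""
        return self.mu_s_prime / (1.0 - self.g)


@dataclass(frozen=True)
class McConfig:
    """Photon budget and termination policy for one simulation."""

    n_photons: int = 100_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    record_paths: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must be in (0, 1)")


@dataclass
class McResult:
    """Detected diffuse reflectance per detector (weight fractions)."""

    reflectance: np.ndarray          # detected weight / launched weight
    standard_error: np.ndarray
    n_detected: np.ndarray           # photons contributing per detector
    n_photons: int
    weight_balance: dict = field(default_factory=dict)
    zero_detection: bool = False
    depth_records: "PathDatabase | None" = None


@dataclass
class PathDatabase:
    """Per detected photon: detector id, total path length, maximum depth,
    and exit weight at zero absorption (white Monte Carlo support)."""

    detector_id: np.ndarray        # int
    path_length_mm: np.ndarray
    max_depth_mm: np.ndarray
    exit_weight: np.ndarray        # expected detected weight per record
    n_photons: int
    seed: int
    geometry_hash: str
    sds_mm: tuple[float, ...]
    mu_s_prime: float = 0.0
    g: float = 0.8
    photon_id: np.ndarray | None = None  # launch index, for per-photon SE

    def __post_init__(self) -> None:
        n = len(self.detector_id)
        if not (len(self.path_length_mm) == len(self.max_depth_mm)
                == len(self.exit_weight) == n):
            raise ValueError("ragged path database columns")
        if self.photon_id is not None and len(self.photon_id) != n:
            raise ValueError("ragged path database columns")

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            detector_id=self.detector_id,
            path_length_mm=self.path_length_mm,
            max_depth_mm=self.max_depth_mm,
            exit_weight=self.exit_weight,
            photon_id=(self.photon_id if self.photon_id is not None
                       else np.arange(len(self.detector_id))),
            meta=np.array([self.n_photons, self.seed,
                           self.mu_s_prime, self.g], dtype=float),
            sds_mm=np.array(self.sds_mm, dtype=float),
            geometry_hash=np.array([self.geometry_hash]),
        )

    @classmethod
    def load(cls, path: str | Path,
             expect_geometry: "ProbeGeometry | None" = None) -> "PathDatabase":
        with np.load(path, allow_pickle=False) as z:
            gh = str(z["geometry_hash"][0])
            if expect_geometry is not None and gh != expect_geometry.geometry_hash():
                raise ValueError(
                    f"geometry hash mismatch: file {gh}, "
                    f"expected {expect_geometry.geometry_hash()}")
            meta = z["meta"]
            return cls(
                detector_id=z["detector_id"],
                path_length_mm=z["path_length_mm"],
                max_depth_mm=z["max_depth_mm"],
                exit_weight=z["exit_weight"],
                photon_id=z["photon_id"] if "photon_id" in z else None,
                n_photons=int(meta[0]),
                seed=int(meta[1]),
                geometry_hash=gh,
                sds_mm=tuple(z["sds_mm"].tolist()),
                mu_s_prime=float(meta[2]),
                g=float(meta[3]),
            )


@njit(cache=False)
def _hg_cosine(g: float, u: float) -> float:
    if g < 1e-9:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


def sample_hg_cosine(g: float, u) -> np.ndarray | float:
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine.

    ``u`` is a uniform variate in [0, 1) (scalar or array).  For g = 0 the
    distribution is isotropic (cos = 2u - 1); the mean cosine equals g.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError("g must be in [0, 1)")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr >= 1)):
        raise ValueError("u must be in [0, 1)")
    if g < 1e-9:
        out = 2.0 * u_arr - 1.0
    else:
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - t * t) / (2.0 * g), -1.0, 1.0)
    return float(out) if np.isscalar(u) else out


@njit(cache=False)
def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, internal incidence, n_rel = n_in/n_out."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


# Record-level Russian roulette threshold: next-event contributions below
# this weight are kept with probability contrib/threshold (boosted to the
# threshold).  Bounds the path-record count at a negligible variance cost.
_RECORD_W_MIN = 3e-4


@njit(cache=False, fastmath=True)
def _mc_kernel(seed, n_photons, mu_a, mu_s, g,
               src_radius, det_radius, sds, cos_na_launch, cos_na_det,
               n_rel, matched,
               w_threshold, p_survive, max_path,
               path_roulette_step, path_roulette_survival, record):
    """Single-threaded photon loop with next-event detection.

    Returns per-detector sums (per-photon aggregated, for honest standard
    errors), the weight balance, and the flat path-record arrays when
    ``record`` is set.  The random-number stream is consumed identically
    whether or not records are kept, so a recorded run reproduces the
    reflectance of an unrecorded run with the same seed bit-for-bit.
    """
    np.random.seed(seed)
    n_det = sds.shape[0]
    sum_w = np.zeros(n_det)
    sum_w2 = np.zeros(n_det)
    n_hit = np.zeros(n_det, dtype=np.int64)
    photon_det = np.zeros(n_det)  # per-photon detected weight

    absorbed = 0.0
    exited = 0.0          # all weight leaving through the surface
    truncated = 0.0
    roulette_net = 0.0
    lost_records = 0.0    # record weight dropped on buffer overflow

    cap = 6 * n_photons + 64 if record else 1
    rec_det = np.empty(cap, dtype=np.int64)
    rec_pho = np.empty(cap, dtype=np.int64)
    rec_len = np.empty(cap, dtype=np.float64)
    rec_dep = np.empty(cap, dtype=np.float64)
    rec_wgt = np.empty(cap, dtype=np.float64)
    n_rec = 0

    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    omega = 2.0 * np.pi * (1.0 - cos_na_det)  # acceptance-cone solid angle

    for ip in range(n_photons):
        # launch: uniform over source face, uniform solid angle within cone
        r = src_radius * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = 0.0
        cz = 1.0 - np.random.random() * (1.0 - cos_na_launch)
        sz = np.sqrt(1.0 - cz * cz)
        phi = 2.0 * np.pi * np.random.random()
        ux = sz * np.cos(phi)
        uy = sz * np.sin(phi)
        uz = cz

        w = 1.0
        path = 0.0
        max_depth = 0.0
        next_path_roulette = path_roulette_step
        for d in range(n_det):
            photon_det[d] = 0.0
        alive = True

        while alive:
            s = -np.log(1.0 - np.random.random()) / mu_t
            while True:
                z_new = z + uz * s
                if uz < 0.0 and z_new <= 0.0:
                    # reaches the surface within this step
                    s_b = -z / uz
                    x += ux * s_b
                    y += uy * s_b
                    z = 0.0
                    path += s_b
                    s -= s_b
                    refl = 0.0
                    if not matched:
                        refl = _fresnel_unpolarized(-uz, n_rel)
                    if matched or np.random.random() >= refl:
                        # transmitted: pure escape (detection is tallied by
                        # the next-event estimator at scattering events)
                        exited += w
                        alive = False
                        break
                    # internally reflected: fold and continue remaining step
                    uz = -uz
                    continue
                # full step inside the medium
                x += ux * s
                y += uy * s
                z = z_new
                path += s
                if z > max_depth:
                    max_depth = z
                break

            if not alive:
                break
            if path > max_path:
                truncated += w
                break
            while path > next_path_roulette:
                next_path_roulette += path_roulette_step
                if np.random.random() < path_roulette_survival:
                    roulette_net -= w * (1.0 / path_roulette_survival - 1.0)
                    w /= path_roulette_survival
                else:
                    roulette_net += w
                    alive = False
                    break
            if not alive:
                break

            # interaction: albedo weighting, next-event detection, HG scatter
            if mu_a > 0.0:
                absorbed += w * (1.0 - albedo)
                w *= albedo

            # -- next-event estimation: one direction uniform in the
            #    upward acceptance cone stands in for the cone integral
            zeta = cos_na_det + np.random.random() * (1.0 - cos_na_det)
            szn = np.sqrt(1.0 - zeta * zeta)
            psi_ne = 2.0 * np.pi * np.random.random()
            ex = szn * np.cos(psi_ne)
            ey = szn * np.sin(psi_ne)
            # cone direction (ex, ey, -zeta); HG density at angle to u
            cos_chi = ux * ex + uy * ey + uz * (-zeta)
            g2 = g * g
            p_hg = (1.0 - g2) / (4.0 * np.pi
                                 * (1.0 + g2 - 2.0 * g * cos_chi) ** 1.5)
            t_esc = z / zeta
            if t_esc * mu_t < 30.0:  # else the escape factor underflows
                fres = 1.0
                if not matched:
                    fres = 1.0 - _fresnel_unpolarized(zeta, n_rel)
                base = w * p_hg * omega * np.exp(-mu_t * t_esc) * fres
                if base > 0.0:
                    xe = x + ex * t_esc
                    ye = y + ey * t_esc
                    rr = np.sqrt(xe * xe + ye * ye)
                    for d in range(n_det):
                        dd = sds[d]
                        if np.abs(rr - dd) < det_radius:
                            num = (rr * rr + dd * dd
                                   - det_radius * det_radius)
                            carg = num / (2.0 * rr * dd)
                            if carg < -1.0:
                                carg = -1.0
                            elif carg > 1.0:
                                carg = 1.0
                            contrib = base * np.arccos(carg) / np.pi
                            # record-level roulette bounds the buffer
                            if contrib < _RECORD_W_MIN:
                                if (np.random.random()
                                        < contrib / _RECORD_W_MIN):
                                    contrib = _RECORD_W_MIN
                                else:
                                    contrib = 0.0
                            if contrib > 0.0:
                                photon_det[d] += contrib
                                if record:
                                    if n_rec < cap:
                                        rec_det[n_rec] = d
                                        rec_pho[n_rec] = ip
                                        rec_len[n_rec] = path + t_esc
                                        rec_dep[n_rec] = max_depth
                                        rec_wgt[n_rec] = contrib
                                        n_rec += 1
                                    else:
                                        lost_records += contrib

            # -- actual scatter
            ct = _hg_cosine(g, np.random.random())
            st = np.sqrt(1.0 - ct * ct)
            psi = 2.0 * np.pi * np.random.random()
            cp = np.cos(psi)
            sp = np.sin(psi)
            if np.abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -st * cp * den + uz * ct
                ux, uy, uz = ux_n, uy_n, uz_n
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm

            if w < w_threshold:
                if np.random.random() < p_survive:
                    roulette_net -= w * (1.0 / p_survive - 1.0)
                    w /= p_survive
                else:
                    roulette_net += w
                    break

        for d in range(n_det):
            c = photon_det[d]
            if c > 0.0:
                sum_w[d] += c
                sum_w2[d] += c * c
                n_hit[d] += 1

    return (sum_w, sum_w2, n_hit, absorbed, exited, truncated, roulette_net,
            lost_records, rec_det[:n_rec], rec_pho[:n_rec], rec_len[:n_rec],
            rec_dep[:n_rec], rec_wgt[:n_rec])


def simulate_reflectance(medium: MediumOptics, probe: ProbeGeometry,
                         config: McConfig) -> McResult:
    """Monte Carlo diffuse reflectance at each source-detector separation.

    Reflectance is the detected weight fraction (azimuth-averaged over the
    detector face); deterministic for a fixed seed.  Zero detection at all
    detectors returns a flagged result, not an exception.
    """
    import warnings as _warnings

    sds = np.asarray(probe.sds_mm, dtype=float)
    (sum_w, sum_w2, n_hit, absorbed, exited, truncated, roulette_net,
     lost_records, rdet, rpho, rlen, rdep, rwgt) = _mc_kernel(
        config.seed, config.n_photons, medium.mu_a, medium.mu_s, medium.g,
        probe.fiber_radius_mm, probe.fiber_radius_mm, sds,
        probe.cos_acceptance_tissue, probe.cos_acceptance_tissue,
        probe.n_tissue / probe.n_ambient, probe.matched,
        config.roulette_threshold, config.roulette_survival,
        _MAX_TOTAL_PATH_MM, _PATH_ROULETTE_STEP_MM, _PATH_ROULETTE_SURVIVAL,
        config.record_paths)
    n = config.n_photons
    refl = sum_w / n
    # SE of the mean per-photon contribution (zeros included)
    var = np.maximum(sum_w2 - sum_w**2 / n, 0.0) / max(n - 1, 1)
    se = np.sqrt(var / n)
    detected = float(np.sum(sum_w))
    # the next-event tally is expected weight carved out of surface exits
    balance = {
        "launched": 1.0,
        "detected": detected / n,
        "escaped": (float(exited) - detected) / n,
        "absorbed": float(absorbed) / n,
        "truncated": float(truncated) / n,
        "roulette_net": float(roulette_net) / n,
    }
    if lost_records > 0:
        _warnings.warn(
            f"path-record buffer overflow: {lost_records:.3g} weight lost; "
            "increase the buffer or photon budget", stacklevel=2)
    depth_records = None
    if config.record_paths:
        depth_records = PathDatabase(
            detector_id=rdet, path_length_mm=rlen, max_depth_mm=rdep,
            exit_weight=rwgt, n_photons=n, seed=config.seed,
            geometry_hash=probe.geometry_hash(), sds_mm=tuple(probe.sds_mm),
            mu_s_prime=medium.mu_s_prime, g=medium.g, photon_id=rpho)
    return McResult(reflectance=refl, standard_error=se, n_detected=n_hit,
                    n_photons=n, weight_balance=balance,
                    zero_detection=bool(np.all(n_hit == 0)),
                    depth_records=depth_records)


def build_path_database(medium: MediumOptics, probe: ProbeGeometry,
                        config: McConfig) -> PathDatabase:
    """Scatter-only (mu_a = 0) run recording every detected photon's path
    length and maximum depth — the white-MC database for that mu_s'."""
    if medium.mu_a != 0.0:
        raise ValueError("path database requires mu_a == 0")
    cfg = McConfig(n_photons=config.n_photons, seed=config.seed,
                   roulette_threshold=config.roulette_threshold,
                   roulette_survival=config.roulette_survival,
                   record_paths=True)
    res = simulate_reflectance(medium, probe, cfg)
    assert res.depth_records is not None
    return res.depth_records


def rescale_reflectance(db: PathDatabase, mu_a: float) -> np.ndarray:
    """White-MC reflectance at absorption ``mu_a``: each detected photon is
    reweighted by exp(-mu_a * path_length).  Monotone non-increasing in mu_a."""
    if mu_a < 0:
        raise ValueError("mu_a must be >= 0")
    n_det = len(db.sds_mm)
    out = np.zeros(n_det)
    wts = db.exit_weight * np.exp(-mu_a * db.path_length_mm)
    for d in range(n_det):
        out[d] = wts[db.detector_id == d].sum() / db.n_photons
    return out


def rescale_reflectance_with_se(db: PathDatabase,
                                mu_a: float) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`rescale_reflectance`, also returning per-detector SE.

    Records from the same launched photon are correlated (the local
    estimator can contribute several times along one trajectory), so the
    SE aggregates contributions per photon before computing the spread.
    """
    if mu_a < 0:
        raise ValueError("mu_a must be >= 0")
    n_det = len(db.sds_mm)
    n = db.n_photons
    refl = np.zeros(n_det)
    se = np.zeros(n_det)
    wts = db.exit_weight * np.exp(-mu_a * db.path_length_mm)
    for d in range(n_det):
        m = db.detector_id == d
        c = wts[m]
        if db.photon_id is not None:
            c = np.bincount(db.photon_id[m], weights=c)
            c = c[c > 0]
        s1 = c.sum()
        s2 = (c**2).sum()
        refl[d] = s1 / n
        var = max(s2 - s1**2 / n, 0.0) / max(n - 1, 1)
        se[d] = np.sqrt(var / n)
    return refl, se


def interrogation_depth(db: PathDatabase, mu_a: float,
                        statistic: str = "mean",
                        percentile: float = 90.0) -> np.ndarray:
    """Weighted statistic of detected photons' maximum depths (mm).

    Weights are ``exit_weight * exp(-mu_a * path_length)``; ``statistic``
    is ``"mean"``, ``"median"`` or ``"percentile"`` (weighted quantile).
    Empty detector bins yield NaN with a warning.
    """
    import warnings as _warnings

    if mu_a < 0:
        raise ValueError("mu_a must be >= 0")
    if statistic not in ("mean", "median", "percentile"):
        raise ValueError(f"unknown statistic {statistic!r}")
    q = 50.0 if statistic == "median" else percentile
    n_det = len(db.sds_mm)
    out = np.full(n_det, np.nan)
    w_all = db.exit_weight * np.exp(-mu_a * db.path_length_mm)
    for d in range(n_det):
        m = db.detector_id == d
        if not np.any(m):
            _warnings.warn(f"no detected photons at detector {d}", stacklevel=2)
            continue
        depths = db.max_depth_mm[m]
        w = w_all[m]
        if statistic == "mean":
            out[d] = float(np.average(depths, weights=w))
        else:
            order = np.argsort(depths)
            dep = depths[order]
            cw = np.cumsum(w[order])
            out[d] = float(np.interp(q / 100.0 * cw[-1], cw, dep))
    return out


def diffusion_reflectance(mu_a: float, mu_s_prime: float,
                          rho_mm: np.ndarray | float,
                          reff: float = 0.0) -> np.ndarray | float:
    """Extrapolated-boundary diffusion-approximation spatially resolved
    reflectance R(rho) of a semi-infinite medium (point source, per mm^2).

    Serves as the independent closed-form check on the Monte Carlo ratio
    R(1 mm)/R(2 mm); ``reff`` is the effective Fresnel reflection
    coefficient (0 for an index-matched boundary).
    """
    rho = np.asarray(rho_mm, dtype=float)
    mu_t_prime = mu_a + mu_s_prime
    z0 = 1.0 / mu_t_prime
    D = 1.0 / (3.0 * mu_t_prime)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t_prime)
    A = (1.0 + reff) / (1.0 - reff)
    zb = 2.0 * A * D
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho**2)
    val = (1.0 / (4.0 * np.pi)) * (
        z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    )
    return float(val) if np.isscalar(rho_mm) else val
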