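"""Reflectance database on the optical-property grid and the ANN inverse.

The forward database tabulates probe reflectance (R1, R2) at the two
source-detector separations over a (mu_a, mu_s') grid — mu_a from 0.001 to
1.00 mm^-1 in 0.001 steps and mu_s' from 0.10 to 3.00 mm^-1 in 0.10 steps
when unthinned (30,000 nodes).  One white-Monte-Carlo path database per
mu_s' node supplies every mu_a row by analytic Beer-Lambert reweighting.

The inverse model is a small feed-forward network (2 x 16 tanh units,
L2-penalized) mapping z-scored (log10 R1, log10 R2) to (log10 mu_a,
log10 mu_s'), applied independently at each wavelength of a measured
reflectance spectrum pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .optics import (McConfig, MediumOptics, PathDatabase, ProbeGeometry,
                     build_path_database, rescale_reflectance_with_se)

__all__ = [
    "GridSpec",
    "ReflectanceDatabase",
    "ReflectanceInverter",
    "RecoveredSpectra",
    "build_reflectance_database",
    "train_inverse_model",
    "invert_reflectance",
    "forward_interpolate",
]


@dataclass(frozen=True)
class GridSpec:
    """Optical-property grid.  ``thin_mu_a`` keeps every k-th mu_a node
    (desk-scale default 10 -> 100 x 30 = 3,000 rows); 1 = full grid."""

    mu_a_min: float = 0.001
    mu_a_max: float = 1.00
    mu_a_step: float = 0.001
    mu_s_prime_min: float = 0.10
    mu_s_prime_max: float = 3.00
    mu_s_prime_step: float = 0.10
    thin_mu_a: int = 10
    thin_mu_s_prime: int = 1

    def __post_init__(self) -> None:
        if self.mu_a_step <= 0 or self.mu_s_prime_step <= 0:
            raise ValueError("grid steps must be positive")
        if not (0 < self.mu_a_min < self.mu_a_max):
            raise ValueError("mu_a range must be positive and ordered")
        if not (0 < self.mu_s_prime_min < self.mu_s_prime_max):
            raise ValueError("mu_s_prime range must be positive and ordered")
        if self.thin_mu_a < 1 or self.thin_mu_s_prime < 1:
            raise ValueError("thinning factors must be >= 1")

    def mu_a_values(self) -> np.ndarray:
        n = int(round((self.mu_a_max - self.mu_a_min) / self.mu_a_step)) + 1
        full = np.round(self.mu_a_min + self.mu_a_step * np.arange(n), 9)
        # thin from the top so the last (largest) node is always kept
        return full[::-1][:: self.thin_mu_a][::-1]

    def mu_s_prime_values(self) -> np.ndarray:
        n = int(round((self.mu_s_prime_max - self.mu_s_prime_min)
                      / self.mu_s_prime_step)) + 1
        full = np.round(self.mu_s_prime_min
                        + self.mu_s_prime_step * np.arange(n), 9)
        return full[::-1][:: self.thin_mu_s_prime][::-1]


@dataclass
class ReflectanceDatabase:
    """(mu_a, mu_s') -> (R1, R2) forward table with standard errors."""

    table: pd.DataFrame  # columns mu_a, mu_sp, R1, R2, se1, se2
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"mu_a", "mu_sp", "R1", "R2", "se1", "se2"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"database missing columns {req - set(self.table.columns)}")
        if (self.table[["R1", "R2"]].values < 0).any():
            raise ValueError("reflectance must be nonnegative")
        if self.table.duplicated(["mu_a", "mu_sp"]).any():
            raise ValueError("duplicate (mu_a, mu_s') keys")
        self.table = self.table.sort_values(["mu_sp", "mu_a"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        Path(str(path) + ".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceDatabase":
        path = Path(path)
        table = pd.read_csv(path, sep="\t")
        prov_path = Path(str(path) + ".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(table=table, provenance=prov)


def build_reflectance_database(grid: GridSpec, probe: ProbeGeometry,
                               mc: McConfig,
                               path_dbs: dict[float, PathDatabase] | None = None,
                               ) -> ReflectanceDatabase:
    """Tabulate (R1, R2) over the grid by white-MC rescaling.

    One scatter-only path database is built (or taken from ``path_dbs``)
    per mu_s' node; every mu_a row follows analytically.  Nodes where any
    detector has SE/R > 10% are recorded in the provenance as
    low-precision warnings.
    """
    mu_a_vals = grid.mu_a_values()
    mu_sp_vals = grid.mu_s_prime_values()
    rows = []
    noisy_nodes = 0
    for i, msp in enumerate(mu_sp_vals):
        if path_dbs is not None and float(msp) in path_dbs:
            db = path_dbs[float(msp)]
        else:
            cfg = McConfig(n_photons=mc.n_photons, seed=mc.seed + i,
                           roulette_threshold=mc.roulette_threshold,
                           roulette_survival=mc.roulette_survival)
            db = build_path_database(MediumOptics(0.0, float(msp)), probe, cfg)
        for ma in mu_a_vals:
            refl, se = rescale_reflectance_with_se(db, float(ma))
            if np.any((refl > 0) & (se / np.maximum(refl, 1e-300) > 0.10)):
                noisy_nodes += 1
            rows.append((float(ma), float(msp), refl[0], refl[1], se[0], se[1]))
    table = pd.DataFrame(rows, columns=["mu_a", "mu_sp", "R1", "R2", "se1", "se2"])
    prov = {
        "geometry_hash": probe.geometry_hash(),
        "n_photons_per_musp": mc.n_photons,
        "seed": mc.seed,
        "n_mu_a": len(mu_a_vals),
        "n_mu_sp": len(mu_sp_vals),
        "noisy_nodes": noisy_nodes,
    }
    if noisy_nodes:
        warnings.warn(
            f"{noisy_nodes} grid nodes have SE/R > 10%; "
            "consider a larger photon budget", stacklevel=2)
    return ReflectanceDatabase(table=table, provenance=prov)


@dataclass
class RecoveredSpectra:
    """Per-wavelength recovered optical properties with domain flags.

    Out-of-domain wavelengths (reflectance pair outside the training cloud
    in log space, or nonpositive reflectance) carry NaN, never a silent
    extrapolation.
    """

    wavelength_nm: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    out_of_domain: np.ndarray  # bool per wavelength


class ReflectanceInverter:
    """Feed-forward inverse model (R1, R2) -> (mu_a, mu_s').

    sklearn-style estimator: ``fit(db)`` trains on a
    :class:`ReflectanceDatabase`; ``predict(R)`` maps an (n, 2) array of
    reflectance pairs to (n, 2) optical properties.  Inputs and outputs
    live in z-scored log10 space internally.  Prediction is explicit
    matrix algebra over the stored weights, so a serialized model
    reproduces predictions bit-for-bit.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden architecture (default (16, 16), tanh).
    alpha : float
        L2 weight penalty.
    validation_fraction : float
        Held-out fraction used for the stored validation loss.
    random_state : int
        Training seed (weight init and the validation split).
    """

    def __init__(self, hidden_layer_sizes=(16, 16), alpha=1e-5,
                 validation_fraction=0.1, random_state=0, max_iter=4000):
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.alpha = alpha
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.max_iter = max_iter

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep=True):
        return {
            "hidden_layer_sizes": self.hidden_layer_sizes,
            "alpha": self.alpha,
            "validation_fraction": self.validation_fraction,
            "random_state": self.random_state,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- training ---------------------------------------------------------
    def fit(self, db: ReflectanceDatabase) -> "ReflectanceInverter":
        from sklearn.neural_network import MLPRegressor

        t = db.table
        pos = (t["R1"] > 0) & (t["R2"] > 0)
        t = t[pos]
        if len(t) < 100:
            raise ValueError(
                f"insufficient data: {len(t)} usable rows (need >= 100)")
        X = np.log10(t[["R1", "R2"]].values)
        Y = np.log10(t[["mu_a", "mu_sp"]].values)

        rng = np.random.RandomState(self.random_state)
        n = len(X)
        idx = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        val_idx, train_idx = idx[:n_val], idx[n_val:]

        self.x_mean_ = X[train_idx].mean(axis=0)
        self.x_scale_ = X[train_idx].std(axis=0)
        self.y_mean_ = Y[train_idx].mean(axis=0)
        self.y_scale_ = Y[train_idx].std(axis=0)
        if not (np.all(np.isfinite(self.x_scale_)) and np.all(self.x_scale_ > 0)
                and np.all(self.y_scale_ > 0)):
            raise ValueError("degenerate database: zero variance in log space")
        Xn = (X - self.x_mean_) / self.x_scale_
        Yn = (Y - self.y_mean_) / self.y_scale_

        net = MLPRegressor(hidden_layer_sizes=self.hidden_layer_sizes,
                           activation="tanh", solver="lbfgs",
                           alpha=self.alpha, max_iter=self.max_iter,
                           tol=1e-9, random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs max_iter convergence noise
            net.fit(Xn[train_idx], Yn[train_idx])

        self.coefs_ = [np.array(c, dtype=float) for c in net.coefs_]
        self.intercepts_ = [np.array(b, dtype=float) for b in net.intercepts_]
        val_pred = self._forward(Xn[val_idx])
        self.validation_loss_ = float(np.mean((val_pred - Yn[val_idx]) ** 2))
        if not np.isfinite(self.validation_loss_):
            raise RuntimeError(
                "training diverged: non-finite validation loss "
                f"(alpha={self.alpha}, seed={self.random_state})")
        # training-domain bounding box in log-reflectance space
        self.domain_min_ = X.min(axis=0)
        self.domain_max_ = X.max(axis=0)
        self.n_train_ = len(train_idx)
        return self

    def _forward(self, Xn: np.ndarray) -> np.ndarray:
        h = Xn
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            h = np.tanh(h @ W + b)
        return h @ self.coefs_[-1] + self.intercepts_[-1]

    # -- inference --------------------------------------------------------
    def predict(self, reflectance: np.ndarray,
                return_flags: bool = False):
        """Map (n, 2) reflectance pairs to (n, 2) (mu_a, mu_s') in mm^-1.

        Pairs with nonpositive reflectance or outside the training-domain
        bounding box in log space yield NaN (flagged when
        ``return_flags``); in-domain pairs are inverted independently.
        """
        self._check_fitted()
        R = np.atleast_2d(np.asarray(reflectance, dtype=float))
        if R.shape[1] != 2:
            raise ValueError("expected shape (n, 2): columns R1, R2")
        n = len(R)
        out = np.full((n, 2), np.nan)
        bad = ~np.all(np.isfinite(R) & (R > 0), axis=1)
        logR = np.full_like(R, np.nan)
        logR[~bad] = np.log10(R[~bad])
        oob = bad.copy()
        inb = ~bad
        inside = np.all((logR[inb] >= self.domain_min_ - 1e-12)
                        & (logR[inb] <= self.domain_max_ + 1e-12), axis=1)
        oob[np.flatnonzero(inb)[~inside]] = True
        good = ~oob
        if np.any(good):
            Xn = (logR[good] - self.x_mean_) / self.x_scale_
            Yn = self._forward(Xn)
            out[good] = 10.0 ** (Yn * self.y_scale_ + self.y_mean_)
        if return_flags:
            return out, oob
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "coefs_"):
            raise RuntimeError("model is not fitted")

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        doc = {
            "format": "skindrs-inverse-model-v1",
            "params": {**self.get_params(),
                       "hidden_layer_sizes": list(self.hidden_layer_sizes)},
            "coefs": [c.tolist() for c in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "x_mean": self.x_mean_.tolist(),
            "x_scale": self.x_scale_.tolist(),
            "y_mean": self.y_mean_.tolist(),
            "y_scale": self.y_scale_.tolist(),
            "domain_min": self.domain_min_.tolist(),
            "domain_max": self.domain_max_.tolist(),
            "validation_loss": self.validation_loss_,
            "n_train": self.n_train_,
        }
        Path(path).write_text(json.dumps(doc) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceInverter":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "skindrs-inverse-model-v1":
            raise ValueError(f"unrecognized model format in {path}")
        params = dict(doc["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        model.coefs_ = [np.array(c, dtype=float) for c in doc["coefs"]]
        model.intercepts_ = [np.array(b, dtype=float) for b in doc["intercepts"]]
        model.x_mean_ = np.array(doc["x_mean"])
        model.x_scale_ = np.array(doc["x_scale"])
        model.y_mean_ = np.array(doc["y_mean"])
        model.y_scale_ = np.array(doc["y_scale"])
        model.domain_min_ = np.array(doc["domain_min"])
        model.domain_max_ = np.array(doc["domain_max"])
        model.validation_loss_ = doc["validation_loss"]
        model.n_train_ = doc["n_train"]
        return model


def train_inverse_model(db: ReflectanceDatabase, random_state: int = 0,
                        **params) -> ReflectanceInverter:
    """Train the default inverse network on a reflectance database."""
    return ReflectanceInverter(random_state=random_state, **params).fit(db)


def invert_reflectance(model: ReflectanceInverter, wavelength_nm: np.ndarray,
                       r1: np.ndarray, r2: np.ndarray) -> RecoveredSpectra:
    """Per-wavelength inversion of a two-SDS reflectance spectrum pair."""
    wl = np.asarray(wavelength_nm, dtype=float)
    R = np.column_stack([np.asarray(r1, float), np.asarray(r2, float)])
    if len(R) != len(wl):
        raise ValueError("wavelength and reflectance lengths differ")
    props, flags = model.predict(R, return_flags=True)
    return RecoveredSpectra(wavelength_nm=wl, mu_a=props[:, 0],
                            mu_s_prime=props[:, 1], out_of_domain=flags)


class _ForwardSurrogate:
    """Bilinear interpolator over a reflectance database grid."""

    def __init__(self, db: ReflectanceDatabase):
        t = db.table
        mu_a = np.unique(t["mu_a"].values)
        mu_sp = np.unique(t["mu_sp"].values)
        if len(t) != len(mu_a) * len(mu_sp):
            raise ValueError("database is not a complete rectangular grid")
        shape = (len(mu_sp), len(mu_a))
        r1 = t["R1"].values.reshape(shape)
        r2 = t["R2"].values.reshape(shape)
        self._itp1 = RegularGridInterpolator((mu_sp, mu_a), r1,
                                             bounds_error=True)
        self._itp2 = RegularGridInterpolator((mu_sp, mu_a), r2,
                                             bounds_error=True)
        self.mu_a_bounds = (mu_a[0], mu_a[-1])
        self.mu_sp_bounds = (mu_sp[0], mu_sp[-1])

    def __call__(self, mu_a, mu_s_prime):
        msp, ma = np.broadcast_arrays(np.asarray(mu_s_prime, float),
                                      np.asarray(mu_a, float))
        pts = np.column_stack([np.ravel(msp), np.ravel(ma)])
        return self._itp1(pts), self._itp2(pts)


def forward_interpolate(db: ReflectanceDatabase, mu_a, mu_s_prime):
    """Bilinear (R1, R2) interpolation in (mu_a, mu_s'); exact at nodes.

    Out-of-bounds queries raise a range error.  The interpolator is cached
    on the database object.
    """
    surrogate = getattr(db, "_surrogate", None)
    if surrogate is None:
        surrogate = _ForwardSurrogate(db)
        db._surrogate = surrogate
    return surrogate(mu_a, mu_s_prime)
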