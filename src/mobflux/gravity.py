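"""Stratified gravity models for origin-destination trip counts.

The gravity model predicts the expected number of trips between origin i and
destination j as

    T_ij = theta * P_i^alpha * P_j^beta * f(d_ij)

with a decaying deterrence kernel f, either power-law ``d^-gamma`` or
exponential ``exp(-d/D)`` (D is the deterrence distance in km). In the
stratified variants the exponents (alpha, beta) and the decay parameter vary
by trip category — urbanicity (4 categories), regional (2), or
regional-urbanicity (8) — while theta remains a single shared proportionality
constant (stratifying theta as well would not be identifiable alongside
per-category exponents).

Populations enter as raw person counts; theta absorbs their scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .geography import Geography, ValidationError
from .trips import TripMatrix
from .typology import SCHEME_CATEGORIES, TripTypology

KERNELS = ("power", "exponential")
SCHEMES = tuple(SCHEME_CATEGORIES)


@dataclass(frozen=True)
class GravityParams:
    """Parameters of one gravity-model variant.

    ``alpha``, ``beta`` and ``decay`` hold one entry per trip category
    (1 for basic, 4 urbanicity, 2 regional, 8 regional-urbanicity); ``decay``
    is the power exponent gamma or the exponential deterrence distance D (km).
    """

    theta: float
    alpha: np.ndarray
    beta: np.ndarray
    decay: np.ndarray
    kernel: str = "power"
    scheme: str = "basic"

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValidationError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.scheme not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        c = SCHEME_CATEGORIES[self.scheme]
        for nm in ("alpha", "beta", "decay"):
            v = np.atleast_1d(np.asarray(getattr(self, nm), dtype=float))
            if v.size != c:
                raise ValidationError(f"{nm} must have {c} entries for scheme {self.scheme!r}, got {v.size}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{nm} must be finite")
            object.__setattr__(self, nm, v)
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValidationError(f"theta must be positive and finite, got {self.theta}")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValidationError("alpha and beta must be non-negative")
        if self.kernel == "exponential" and np.any(self.decay <= 0):
            raise ValidationError("deterrence distance D must be > 0")
        if self.kernel == "power" and np.any(self.decay < 0):
            raise ValidationError("power exponent gamma must be >= 0")

    @property
    def n_categories(self) -> int:
        return SCHEME_CATEGORIES[self.scheme]


def count_parameters(params: GravityParams) -> int:
    """Free parameters: shared theta plus (alpha, beta, decay) per category."""
    return 1 + 3 * params.n_categories


def distance_kernel(d: np.ndarray, decay: np.ndarray, kernel: str) -> np.ndarray:
    """Decaying deterrence f(d): ``d**-gamma`` or ``exp(-d/D)``, elementwise."""
    d = np.asarray(d, dtype=float)
    if kernel == "power":
        return np.power(d, -np.asarray(decay, dtype=float))
    if kernel == "exponential":
        return np.exp(-d / np.asarray(decay, dtype=float))
    raise ValidationError(f"unknown kernel {kernel!r}")


def gravity_predict(params: GravityParams, geo: Geography, typology: TripTypology) -> TripMatrix:
    """Expected trip counts T_ij for every ordered district pair (diagonal absent)."""
    if typology.ids != geo.ids:
        raise ValidationError("typology and geography refer to different districts")
    cat = typology.index_for_scheme(params.scheme)
    off = cat >= 0
    if params.kernel == "power" and np.any((geo.distance_matrix == 0) & off & (params.decay[np.clip(cat, 0, None)] > 0)):
        raise ValidationError("power kernel is singular at zero distance between distinct districts")
    P = geo.populations
    c = np.clip(cat, 0, None)
    with np.errstate(divide="ignore"):
        T = (
            params.theta
            * np.power(P[:, None], params.alpha[c])
            * np.power(P[None, :], params.beta[c])
            * distance_kernel(geo.distance_matrix, params.decay[c], params.kernel)
        )
    T[~off] = np.nan
    if not np.all(np.isfinite(T[off])):
        raise ValidationError("gravity prediction produced non-finite expected counts")
    return TripMatrix(list(geo.ids), T)


# ---------------------------------------------------------------------------
# parameter file IO


def params_to_yaml(params: GravityParams, path) -> None:
    doc = {
        "model": "gravity",
        "scheme": params.scheme,
        "kernel": params.kernel,
        "theta": float(params.theta),
        "categories": [
            {"category": c + 1, "alpha": float(a), "beta": float(b), "decay": float(g)}
            for c, (a, b, g) in enumerate(zip(params.alpha, params.beta, params.decay))
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def params_from_yaml(path) -> GravityParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cats = sorted(doc["categories"], key=lambda r: r["category"])
    return GravityParams(
        theta=float(doc["theta"]),
        alpha=np.array([r["alpha"] for r in cats]),
        beta=np.array([r["beta"] for r in cats]),
        decay=np.array([r["decay"] for r in cats]),
        kernel=doc["kernel"],
        scheme=doc["scheme"],
    )


def params_to_frame(params: GravityParams) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": np.arange(1, params.n_categories + 1),
            "alpha": params.alpha,
            "beta": params.beta,
            "decay": params.decay,
        }
    )
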