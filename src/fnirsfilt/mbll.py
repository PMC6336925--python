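"""Modified Beer–Lambert law: intensity -> ΔOD -> concentration, both ways.

The differential modified Beer–Lambert law links the change in optical
density at wavelength λ to chromophore concentration changes:

    ΔOD_λ = (ε_HbO2,λ · ΔHbO2 + ε_HbR,λ · ΔHbR) · d · DPF

with decadic molar extinction coefficients ε (1/(M·cm)), source–detector
separation d (cm) and differential pathlength factor DPF. With two
wavelengths this is an invertible 2×2 linear system per sample, so the
ΔOD↔concentration maps are exact inverses and commute with any LTI filter —
the mechanism behind the finding that filtering ΔOD or concentration makes
no difference to the estimated β.

Default extinction values at 705/830 nm are decadic molar coefficients from
the standard compiled hemoglobin tabulation (Prahl); they are configurable
and no result in this package depends on the specific numbers (all
correctness checks are round-trip and linearity properties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ChannelSeries

__all__ = [
    "MBLLParams",
    "load_extinction_table",
    "od_from_intensity",
    "conc_from_od",
    "od_from_conc",
    "BeerLambert",
]

_COND_LIMIT = 1e12


def load_extinction_table(path=None) -> dict:
    """Load {wavelength: (eps_hbo2, eps_hbr)} from a CSV table.

    The packaged default covers 705 and 830 nm (decadic, 1/(M·cm)).
    """
    if path is None:
        ref = resources.files("fnirsfilt.data") / "extinction_hbo2_hbr.csv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = {}
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    for line in lines[1:]:
        wl, e1, e2 = line.split(",")
        table[float(wl)] = (float(e1), float(e2))
    return table


def _default_extinction() -> np.ndarray:
    table = load_extinction_table()
    return np.array([table[705.0], table[830.0]])


@dataclass(frozen=True)
class MBLLParams:
    """Geometry and optics of the measurement.

    ``extinction`` is the 2×2 matrix with rows = wavelengths and columns =
    (HbO2, HbR), decadic, in 1/(M·cm). Defaults: 705/830 nm, 3 cm
    separation, DPF 6, base-10 logarithm.
    """

    wavelengths: tuple = (705.0, 830.0)
    extinction: np.ndarray = field(default_factory=_default_extinction)
    dpf: float = 6.0
    separation: float = 3.0

    def __post_init__(self):
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if np.linalg.cond(ext) > _COND_LIMIT:
            raise ValueError("extinction matrix is singular or near-singular")
        if self.dpf <= 0 or self.separation <= 0:
            raise ValueError("dpf and separation must be positive")
        object.__setattr__(self, "extinction", ext)

    @property
    def system_matrix(self) -> np.ndarray:
        """The 2×2 map concentration -> ΔOD: ε · d · DPF."""
        return self.extinction * (self.separation * self.dpf)


def od_from_intensity(intensity: ChannelSeries, baseline: str = "mean") -> ChannelSeries:
    """ΔOD = −log10(I / I_baseline).

    ``baseline`` is either ``"mean"`` (whole-record mean) or ``"first_n:<k>"``
    (mean of the first k samples).
    """
    vals = intensity.values
    bad = np.nonzero(vals <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive intensity at sample index {bad[0]}")
    if baseline == "mean":
        ref = vals.mean()
    elif baseline.startswith("first_n"):
        k = int(baseline.split(":")[1]) if ":" in baseline else 100
        ref = vals[:k].mean()
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    od = -np.log10(vals / ref)
    return ChannelSeries(od, fs=intensity.fs, kind="OD", wavelength=intensity.wavelength)


def conc_from_od(od_pair, params: MBLLParams = None):
    """Solve the per-sample 2×2 system for (ΔHbO2, ΔHbR) from ΔOD at λ1, λ2."""
    params = params or MBLLParams()
    od1, od2 = od_pair
    if len(od1) != len(od2) or od1.fs != od2.fs:
        raise ValueError("OD series must share length and sampling rate")
    inv = np.linalg.inv(params.system_matrix)
    conc = inv @ np.vstack([od1.values, od2.values])
    hbo = ChannelSeries(conc[0], fs=od1.fs, kind="HbO2")
    hbr = ChannelSeries(conc[1], fs=od1.fs, kind="HbR")
    return hbo, hbr


def od_from_conc(conc_pair, params: MBLLParams = None):
    """Forward map (ΔHbO2, ΔHbR) -> (ΔOD@λ1, ΔOD@λ2); exact inverse of
    :func:`conc_from_od`."""
    params = params or MBLLParams()
    hbo, hbr = conc_pair
    if len(hbo) != len(hbr) or hbo.fs != hbr.fs:
        raise ValueError("concentration series must share length and sampling rate")
    od = params.system_matrix @ np.vstack([hbo.values, hbr.values])
    w1, w2 = params.wavelengths
    od1 = ChannelSeries(od[0], fs=hbo.fs, kind="OD", wavelength=w1)
    od2 = ChannelSeries(od[1], fs=hbo.fs, kind="OD", wavelength=w2)
    return od1, od2


class BeerLambert(BaseEstimator, TransformerMixin):
    """sklearn-style transformer between ΔOD and concentration matrices.

    Operates on arrays of shape (n_samples, 2) with columns (λ1, λ2) in OD
    space or (HbO2, HbR) in concentration space; ``direction`` selects the
    map. Stateless: ``fit`` only validates.
    """

    def __init__(self, direction: str = "od_to_conc", params: MBLLParams = None):
        self.direction = direction
        self.params = params

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected shape (n_samples, 2)")
        if self.direction not in ("od_to_conc", "conc_to_od"):
            raise ValueError(f"unknown direction {self.direction!r}")
        p = self.params or MBLLParams()
        m = p.system_matrix
        self.matrix_ = np.linalg.inv(m) if self.direction == "od_to_conc" else m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (self.matrix_ @ X.T).T

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return (np.linalg.inv(self.matrix_) @ X.T).T
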