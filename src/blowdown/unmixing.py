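"""Linear spectral mixture analysis and change-in-NPV disturbance signals.

Each reflectance pixel is modelled as a linear mixture of endmember
spectra — photosynthetic vegetation (PV), non-photosynthetic vegetation
(NPV) and shade — solved per pixel by least squares under the hard
equality constraint that fractions sum to one.  Negative fractions are
allowed (and logged), matching sum-to-one-only unmixing as implemented in
standard remote-sensing toolchains.

The disturbance signal is the per-pixel change in the NPV fraction
(post minus pre): storm-killed trees expose dead wood, raising NPV.  A
one-sample t-test asks whether mean dNPV is positive, and an OLS
regression of dNPV on carbon loss measures how much of the carbon signal
the optical change explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import MultibandRaster

logger = logging.getLogger(__name__)

__all__ = [
    "EndmemberSet",
    "FractionMap",
    "unmix",
    "delta_npv",
    "test_positive_dnpv",
    "TTestResult",
    "regress_dnpv_on_acd_loss",
    "RegressionResult",
    "read_endmembers_csv",
    "write_endmembers_csv",
]


@dataclass
class EndmemberSet:
    """One reflectance spectrum per endmember over the sensor bands."""

    spectra: np.ndarray            # (n_endmembers, n_bands)
    names: list[str]
    bands: list[str]

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be (n_endmembers, n_bands)")
        m, nb = self.spectra.shape
        if nb < 2:
            raise ValueError("need at least 2 bands")
        if len(self.names) != m or len(self.bands) != nb:
            raise ValueError("names/bands lengths do not match spectra")
        if np.any(self.spectra < 0) or np.any(self.spectra > 1):
            raise ValueError("reflectance must lie in [0, 1]")
        if np.linalg.matrix_rank(self.spectra) < m:
            raise ValueError("endmember spectra are linearly dependent")


@dataclass
class FractionMap:
    """Per-pixel endmember fractions (summing to one) and residual RMS."""

    fractions: np.ndarray          # (n_endmembers, rows, cols)
    residual_rms: np.ndarray       # (rows, cols)
    names: list[str]
    resolution_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def band(self, name: str) -> np.ndarray:
        return self.fractions[self.names.index(name)]


def unmix(reflectance: MultibandRaster, endmembers: EndmemberSet) -> FractionMap:
    """Sum-to-one constrained least-squares unmixing of every pixel.

    Solves min ||E^T f - r||^2 subject to 1^T f = 1 through the KKT system;
    the (small) KKT matrix is factored once and applied to all pixels.
    """
    e = endmembers.spectra                    # (m, bands)
    m, nb = e.shape
    if reflectance.n_bands != nb:
        raise ValueError(
            f"band mismatch: raster has {reflectance.n_bands}, endmembers {nb}"
        )
    kkt = np.zeros((m + 1, m + 1))
    kkt[:m, :m] = 2.0 * (e @ e.T)
    kkt[:m, m] = 1.0
    kkt[m, :m] = 1.0
    if np.linalg.matrix_rank(kkt) < m + 1:
        raise ValueError("rank-deficient endmember matrix")
    _, rows, cols = reflectance.values.shape
    r = reflectance.values.reshape(nb, -1)    # (bands, npix)
    rhs = np.vstack([2.0 * (e @ r), np.ones((1, r.shape[1]))])
    sol = np.linalg.solve(kkt, rhs)
    f = sol[:m]
    resid = e.T @ f - r
    rms = np.sqrt(np.mean(resid**2, axis=0))
    n_neg = int(np.sum(np.any(f < -1e-12, axis=0)))
    if n_neg:
        logger.info("unmix: %d pixel(s) have a negative fraction (allowed)", n_neg)
    return FractionMap(
        f.reshape(m, rows, cols),
        rms.reshape(rows, cols),
        list(endmembers.names),
        reflectance.resolution_m,
        reflectance.origin,
    )


def delta_npv(pre: FractionMap, post: FractionMap, name: str = "npv") -> np.ndarray:
    """Change in the NPV fraction: post minus pre, per pixel."""
    if pre.fractions.shape != post.fractions.shape or not np.allclose(
        pre.origin, post.origin
    ):
        raise ValueError("fraction maps are not aligned")
    return post.band(name) - pre.band(name)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def test_positive_dnpv(dnpv: np.ndarray) -> TTestResult:
    """Two-sided one-sample t-test of mean dNPV = 0 over valid pixels."""
    x = np.asarray(dnpv, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 valid pixels")
    if np.allclose(x.std(ddof=1), 0.0):
        raise ValueError("degenerate sample: zero variance")
    res = stats.ttest_1samp(x, 0.0)
    return TTestResult(float(res.statistic), int(x.size - 1), float(res.pvalue))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def regress_dnpv_on_acd_loss(dnpv, acd_change) -> RegressionResult:
    """OLS of dNPV against ACD change over paired valid cells."""
    x = np.asarray(acd_change, dtype=float).ravel()
    y = np.asarray(dnpv, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired cells")
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue**2), float(res.pvalue), int(x.size))


# ---------------------------------------------------------------------------
# Endmember CSV I/O: long format `endmember,band,reflectance`
# ---------------------------------------------------------------------------

def write_endmembers_csv(endmembers: EndmemberSet, path) -> None:
    rows = [
        {"endmember": em, "band": band, "reflectance": endmembers.spectra[i, j]}
        for i, em in enumerate(endmembers.names)
        for j, band in enumerate(endmembers.bands)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_endmembers_csv(path) -> EndmemberSet:
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["endmember"]))
    bands = list(dict.fromkeys(df["band"]))
    spectra = np.array(
        [
            [float(df[(df.endmember == em) & (df.band == b)]["reflectance"].iloc[0])
             for b in bands]
            for em in names
        ]
    )
    return EndmemberSet(spectra, names, bands)
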