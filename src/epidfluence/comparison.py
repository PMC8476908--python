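"""Dose-difference and structural-similarity maps between fluence-map pairs.

Given a baseline map ``x`` and an errored map ``y`` the module computes

* the dose-difference map ``DD = |x - y|`` and
* the SSIM decomposition: luminance ``l``, contrast ``c``, structure ``s``
  and the combined map ``SSIM = l^alpha * c^beta * s^gamma``,

with the local moments (means, standard deviations, covariance) taken over
a sliding uniform square window.  Stabilising constants ``C1 = (K1*L)^2``,
``C2 = (K2*L)^2`` and ``C3 = C2/2`` guard the denominators, with ``L`` the
dose dynamic range (the 200 cGy fraction dose by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter

from .core import FRACTION_DOSE_CGY, FluenceMap, as_pixels

BorderMode = Literal["reflect", "valid"]


@dataclass(frozen=True)
class SsimConfig:
    """Window size, stabilising constants and exponents for SSIM maps."""

    window: int = 11
    k1: float = 0.01
    k2: float = 0.03
    dose_scale: float = FRACTION_DOSE_CGY  # the L constant, in cGy
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    border: BorderMode = "reflect"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window side must be odd and >= 3, got {self.window}")
        if self.k1 <= 0 or self.k2 <= 0 or self.dose_scale <= 0:
            raise ValueError("K1, K2 and the dose scale L must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dose_scale) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dose_scale) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass
class ComparisonMaps:
    """DD plus the SSIM component and combined maps for one map pair."""

    dd: np.ndarray
    luminance: np.ndarray
    contrast: np.ndarray
    structure: np.ndarray
    ssim: np.ndarray
    baseline: FluenceMap | None = None
    errored: FluenceMap | None = None
    config: SsimConfig = field(default_factory=SsimConfig)

    #: component-name -> map, in the canonical ordering used everywhere.
    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "dd": self.dd,
            "luminance": self.luminance,
            "contrast": self.contrast,
            "structure": self.structure,
            "ssim": self.ssim,
        }


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise ValueError(f"expected 2D maps, got {x.ndim}D")


def dd_map(baseline: FluenceMap | np.ndarray, errored: FluenceMap | np.ndarray) -> np.ndarray:
    """Pointwise absolute dose difference |V_x - V_y| (symmetric)."""
    x, y = as_pixels(baseline), as_pixels(errored)
    _check_pair(x, y)
    return np.abs(x - y)


def local_moments(
    x: FluenceMap | np.ndarray,
    y: FluenceMap | np.ndarray,
    cfg: SsimConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window means, standard deviations and covariance.

    Uniform (unweighted) square window of side ``cfg.window``; borders are
    handled by reflection padding.  Returns ``(mu_x, mu_y, sigma_x,
    sigma_y, cov_xy)``.
    """
    cfg = cfg or SsimConfig()
    # double precision throughout: the x == y identities (SSIM exactly 1)
    # rely on variance and covariance agreeing to rounding
    x = as_pixels(x).astype(np.float64, copy=False)
    y = as_pixels(y).astype(np.float64, copy=False)
    _check_pair(x, y)
    if min(x.shape) < cfg.window:
        raise ValueError(
            f"window {cfg.window} does not fit in image of shape {x.shape}"
        )

    def _mean(a: np.ndarray) -> np.ndarray:
        return uniform_filter(a, size=cfg.window, mode="reflect")

    mu_x = _mean(x)
    mu_y = _mean(y)
    # E[a^2] - E[a]^2, clipped: rounding can push tiny variances below zero.
    var_x = np.maximum(_mean(x * x) - mu_x * mu_x, 0.0)
    var_y = np.maximum(_mean(y * y) - mu_y * mu_y, 0.0)
    cov_xy = _mean(x * y) - mu_x * mu_y
    return mu_x, mu_y, np.sqrt(var_x), np.sqrt(var_y), cov_xy


def ssim_components(
    baseline: FluenceMap | np.ndarray,
    errored: FluenceMap | np.ndarray,
    cfg: SsimConfig | None = None,
) -> ComparisonMaps:
    """Compute DD, luminance, contrast, structure and combined SSIM maps.

    l = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)
    c = (2 s_x s_y  + C2) / (s_x^2  + s_y^2  + C2)
    s = (cov_xy + C3)     / (s_x s_y + C3)
    SSIM = l^alpha * c^beta * s^gamma

    With ``border="valid"`` all five maps are cropped by the half-window
    margin so only fully interior windows remain.
    """
    cfg = cfg or SsimConfig()
    x, y = as_pixels(baseline), as_pixels(errored)
    mu_x, mu_y, s_x, s_y, cov = local_moments(x, y, cfg)

    lum = (2 * mu_x * mu_y + cfg.c1) / (mu_x**2 + mu_y**2 + cfg.c1)
    con = (2 * s_x * s_y + cfg.c2) / (s_x**2 + s_y**2 + cfg.c2)
    stru = (cov + cfg.c3) / (s_x * s_y + cfg.c3)
    # structure is computed before exponent weighting; negative values are
    # legitimate (anticorrelated windows), so non-integer gamma is applied
    # via sign-preserving power.
    ssim = (
        np.power(lum, cfg.alpha)
        * np.power(con, cfg.beta)
        * np.sign(stru) * np.power(np.abs(stru), cfg.gamma)
    )
    dd = np.abs(x - y)

    maps = {"dd": dd, "luminance": lum, "contrast": con, "structure": stru, "ssim": ssim}
    if cfg.border == "valid":
        m = cfg.window // 2
        maps = {k: v[m:-m, m:-m] for k, v in maps.items()}

    return ComparisonMaps(
        dd=maps["dd"],
        luminance=maps["luminance"],
        contrast=maps["contrast"],
        structure=maps["structure"],
        ssim=maps["ssim"],
        baseline=baseline if isinstance(baseline, FluenceMap) else None,
        errored=errored if isinstance(errored, FluenceMap) else None,
        config=cfg,
    )
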