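"""Window-based Bayesian GWAS: regional variances and WPPA.

The genome is tiled into non-overlapping physical windows (1 Mb by
default). In every retained MCMC draw, the regional genotypic values of a
window are built from the sampled marker effects at the markers it
contains, their population variance across genotypes is taken, and the
regional share zeta^2 of the draw's total genetic variance is formed. The
window posterior probability of association (WPPA) is the fraction of draws
in which zeta^2 strictly exceeds the threshold share (1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples
from .noia import NOIADesign
from .posterior import component_values


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    marker_index: tuple[int, ...]

    @property
    def n_markers(self) -> int:
        return len(self.marker_index)


def make_windows(
    chrom: np.ndarray, pos: np.ndarray, size: int = 1_000_000
) -> list[Window]:
    """Non-overlapping tiles [k*size+1, (k+1)*size] per chromosome.

    A marker at exactly (k+1)*size belongs to tile k (1-based inclusive
    coordinates); tiles containing no markers are omitted.
    """
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    windows: list[Window] = []
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        tiles = (pos[idx] - 1) // size
        for t in np.unique(tiles):
            members = idx[tiles == t]
            windows.append(
                Window(
                    chrom=str(c),
                    start=int(t) * size + 1,
                    end=(int(t) + 1) * size,
                    marker_index=tuple(int(m) for m in members),
                )
            )
    return windows


def regional_variance(
    samples: PosteriorSamples,
    design: NOIADesign,
    windows: list[Window],
    component: str = "additive",
) -> np.ndarray:
    """Per-draw regional variance shares zeta^2, one column per window.

    For each draw, the window's genotypic values are W[:, markers] @ effects
    (additive or dominance coefficients), their population variance is the
    regional variance, and it is divided by the draw's total genetic
    variance (variance of the summed genetic value).
    """
    if not windows:
        raise ValueError("empty window list")
    if component == "additive":
        eff, W = samples.a, design.Wa
    elif component == "dominance":
        eff, W = samples.d, design.Wd
    else:
        raise ValueError("component must be 'additive' or 'dominance'")
    if eff is None:
        raise ValueError(f"model has no {component} marker effects")

    total = component_values(samples, design)["total"]
    sigma2_g = total.var(axis=1)  # population variance per draw
    zeta = np.empty((samples.n_draws, len(windows)))
    for q, win in enumerate(windows):
        m = list(win.marker_index)
        g_region = eff[:, m] @ W[:, m].T  # draws x genotypes
        var_region = g_region.var(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zeta[:, q] = np.where(sigma2_g > 0, var_region / sigma2_g, 0.0)
    return zeta


@dataclass
class WindowAssociation:
    chrom: str
    start: int
    end: int
    n_markers: int
    wppa_a: float
    wppa_d: float | None
    threshold: float


def wppa(zeta: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """WPPA per window: fraction of draws with zeta^2 strictly above threshold."""
    zeta = np.asarray(zeta)
    if zeta.shape[0] < 1:
        raise ValueError("need at least one retained draw")
    return (zeta > threshold).mean(axis=0)


def window_associations(
    samples: PosteriorSamples,
    design: NOIADesign,
    windows: list[Window],
    threshold: float = 0.01,
    with_dominance: bool | None = None,
) -> pd.DataFrame:
    """Assemble the WPPA table for additive (and dominance) effects."""
    zeta_a = regional_variance(samples, design, windows, "additive")
    wa = wppa(zeta_a, threshold)
    if with_dominance is None:
        with_dominance = samples.d is not None
    wd = None
    if with_dominance:
        zeta_d = regional_variance(samples, design, windows, "dominance")
        wd = wppa(zeta_d, threshold)
    rows = []
    for q, win in enumerate(windows):
        rows.append(
            {
                "chrom": win.chrom,
                "start": win.start,
                "end": win.end,
                "n_markers": win.n_markers,
                "wppa_a": float(wa[q]),
                "wppa_d": float(wd[q]) if wd is not None else np.nan,
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows)
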