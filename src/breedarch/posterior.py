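"""Posterior variance decomposition and genomic heritability.

Per retained MCMC draw, each component's genotypic values are formed over
all genotypes (marker terms by multiplying the NOIA coefficients with the
sampled effects, kernel terms directly from the sampled random-effect
vectors) and the component variance is the *population* variance (divide by
n) of those values across genotypes. The total genetic variance is the
variance of the summed values — not the sum of component variances, since
components may covary within a draw. Heritability h2 = s2_g / (s2_g + s2_e)
is computed per draw and then summarized, preserving its posterior
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples
from .noia import NOIADesign

COMPONENT_NAMES = {"a": "additive", "d": "dominance", "aa": "add_x_add",
                   "ad": "add_x_dom", "dd": "dom_x_dom"}


def component_values(
    samples: PosteriorSamples, design: NOIADesign | None = None
) -> dict[str, np.ndarray]:
    """Per-draw genotypic values for every component the model carries.

    Returns a dict mapping component key ("a", "d", "aa", "ad", "dd", "gk")
    to a (draws x genotypes) array, plus "total" for their sum.
    """
    out: dict[str, np.ndarray] = {}
    if samples.a is not None:
        if design is None:
            raise ValueError("marker-effect samples need the NOIA design")
        out["a"] = samples.a @ design.Wa.T
    if samples.d is not None:
        out["d"] = samples.d @ design.Wd.T
    for name, u in samples.u_terms.items():
        out[name] = u
    if not out:
        raise ValueError("samples contain no genetic terms")
    total = np.zeros_like(next(iter(out.values())))
    for v in out.values():
        total = total + v
    out["total"] = total
    return out


@dataclass
class VarianceDecomposition:
    """Draw-level variance components and their posterior summaries."""

    draws: pd.DataFrame  # one row per retained draw
    components: list[str]

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.draws.columns:
            v = self.draws[col].to_numpy()
            rows.append(
                {
                    "parameter": col,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v)),
                    "q2.5": float(np.quantile(v, 0.025)),
                    "q97.5": float(np.quantile(v, 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def shares(self) -> pd.DataFrame:
        """Per-draw component shares of the total genetic variance."""
        out = {}
        tot = self.draws["sigma2_g"].to_numpy()
        for c in self.components:
            out[c] = self.draws[f"sigma2_{c}"].to_numpy() / np.where(tot > 0, tot, np.nan)
        return pd.DataFrame(out)


def variance_components(
    samples: PosteriorSamples, design: NOIADesign | None = None
) -> VarianceDecomposition:
    """Decompose each retained draw into variance components.

    Every component variance is the population variance of that component's
    genotypic values across genotypes in the draw; sigma2_g is the variance
    of the total genetic value.
    """
    values = component_values(samples, design)
    if values["total"].shape[1] < 1:
        raise ValueError("no genotypes to take variances over")
    cols = {}
    comps = [k for k in values if k != "total"]
    for k in comps:
        cols[f"sigma2_{k}"] = values[k].var(axis=1)  # population variance
    cols["sigma2_g"] = values["total"].var(axis=1)
    cols["sigma2_e"] = samples.sigma2_e
    denom = cols["sigma2_g"] + samples.sigma2_e
    cols["h2"] = np.where(denom > 0, cols["sigma2_g"] / denom, 0.0)
    return VarianceDecomposition(draws=pd.DataFrame(cols), components=comps)


def genomic_heritability(vd: VarianceDecomposition) -> pd.Series:
    """Posterior summary of h2 (computed ratio-first, per draw)."""
    return vd.summary.loc["h2"]
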