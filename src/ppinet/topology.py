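"""Degree-distribution power-law fitting and scalar topological parameters.

The power-law fit follows the log-log least-squares convention of network
topology tools: a simple linear regression of log10(count) on log10(degree)
over the observed (nonzero-count) degrees, reported as ``y = beta * x**a``
with the R-squared of the log-log regression plus the Pearson correlation
between observed and fitted counts on the original scale.  This is a
descriptive fit, not a maximum-likelihood heavy-tail estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_core import PPINetwork


@dataclass(frozen=True)
class DegreeHistogram:
    """Census of node degrees: (degree, count) pairs with count > 0."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def degrees(self) -> np.ndarray:
        return np.array([k for k, _ in self.pairs], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.pairs], dtype=float)

    @property
    def n_nodes(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the log-log least-squares fit y = beta * x**exponent."""

    beta: float
    exponent: float
    r_squared: float
    correlation: float

    def formula(self) -> str:
        return f"y = {self.beta:.6g}x^{self.exponent:.6g}"


def degree_histogram(net: PPINetwork) -> DegreeHistogram:
    """Exact census of node degrees of a cleaned network."""
    if net.n_nodes == 0:
        raise ValueError("degree histogram of an empty network is undefined")
    census = Counter(d for _, d in net.graph.degree())
    return DegreeHistogram(pairs=tuple(sorted(census.items())))


def fit_power_law(hist: DegreeHistogram) -> PowerLawFit:
    """Fit ``count = beta * degree**a`` by least squares in log10-log10 space.

    Requires at least two distinct degrees.  ``r_squared`` is the coefficient
    of determination of the log-log regression; ``correlation`` is the
    Pearson correlation of observed vs fitted counts on the original scale.
    """
    if len(hist.pairs) < 2:
        raise ValueError("power-law fit needs >= 2 distinct degrees")
    log_k = np.log10(hist.degrees)
    log_c = np.log10(hist.counts)
    fit = stats.linregress(log_k, log_c)
    beta = 10.0 ** fit.intercept
    fitted = beta * hist.degrees**fit.slope
    if np.allclose(hist.counts, fitted, rtol=1e-12, atol=1e-12):
        correlation = 1.0  # degenerate pearsonr on exact fits
    else:
        correlation = float(stats.pearsonr(hist.counts, fitted).statistic)
    return PowerLawFit(
        beta=float(beta),
        exponent=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        correlation=correlation,
    )


def scalar_parameters(net: PPINetwork) -> dict[str, float]:
    """Density, mean clustering coefficient and degree centralization.

    density = 2E / (n(n-1)); clustering is the mean local clustering
    coefficient with degree<2 nodes contributing 0; centralization is the
    Freeman degree centralization [n/(n-2)] * [max_k/(n-1) - density].
    Requires n >= 3.
    """
    import networkx as nx

    n = net.n_nodes
    if n < 3:
        raise ValueError("scalar parameters require at least 3 nodes")
    e = net.n_edges
    density = 2.0 * e / (n * (n - 1))
    clustering = nx.average_clustering(net.graph, count_zeros=True)
    max_k = max(d for _, d in net.graph.degree())
    centralization = (n / (n - 2)) * (max_k / (n - 1) - density)
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "clustering_coefficient": clustering,
        "centralization": centralization,
    }


def topology_report(net: PPINetwork) -> dict[str, object]:
    """One network's row of the topology report: fit + scalar parameters."""
    hist = degree_histogram(net)
    row: dict[str, object] = {"network": net.name}
    row.update(scalar_parameters(net))
    if len(hist.pairs) >= 2:
        fit = fit_power_law(hist)
        row.update(
            {
                "beta": fit.beta,
                "exponent": fit.exponent,
                "r_squared": fit.r_squared,
                "correlation": fit.correlation,
                # the correlation convention is not standardized across tools
                "correlation_definition": "pearson(observed, fitted) on original scale",
            }
        )
    return row
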