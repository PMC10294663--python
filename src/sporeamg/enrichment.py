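"""Per-gene hypergeometric enrichment among phages of spore-forming hosts.

For each KO the question is: given that ``K`` of the ``N`` phages surveyed
infect a spore-forming host, is the gene detected in spore-host phages more
often than drawing its ``n`` carriers uniformly without replacement would
predict?  The upper-tail probability

    P(X >= k),  X ~ Hypergeometric(N, K, n)

is computed exactly with integer arithmetic (no floating-point summation
error), Benjamini-Hochberg adjusted across all tested genes, and a gene is
flagged enriched when the adjusted p falls below ``alpha_adj`` (default
1e-6) AND the gene is detected in more than ``min_n`` phages (default 30).
The sample-size gate guards against tiny-n genes whose extreme p values
rest on a handful of detections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_ingest import GeneCatalogEntry, PresenceMatrix

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "adjust_pvalues",
    "test_all_genes",
    "results_to_frame",
    "plot_volcano",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha_adj: float = 1e-6  # adjusted-p threshold (exclusive)
    min_n: int = 30  # homolog-count threshold (exclusive: n must exceed it)
    adjust_method: str = "BH"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_adj < 1.0:
            raise ValidationError(f"alpha_adj: {self.alpha_adj} not in (0, 1)")
        if self.min_n < 0:
            raise ValidationError(f"min_n: {self.min_n} must be >= 0")
        if self.adjust_method != "BH":
            raise ValidationError(
                f"adjust_method: only 'BH' is supported, got {self.adjust_method!r}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    ko_id: str
    n: int  # phages in which the gene is detected
    k: int  # detections among spore-host phages
    K: int  # spore-host phages
    N: int  # phages surveyed
    p_raw: float
    p_adj: float
    neg_log10_p: float  # -log10(p_raw), the plotted quantity
    enriched: bool


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts spore-host phages among ``n`` drawn without replacement from
    ``N`` phages of which ``K`` are spore-host.  The tail is summed in exact
    integer arithmetic and rounded once to the nearest float, so the result
    is correct to the last bit for any N this package meets in practice.
    """
    if not (0 <= K <= N):
        raise ValidationError(f"K={K} outside [0, N={N}]")
    if not (0 <= n <= N):
        raise ValidationError(f"n={n} outside [0, N={N}]")
    k_min, k_max = max(0, n + K - N), min(n, K)
    if not (k_min <= k <= k_max):
        raise ValidationError(
            f"k={k} outside support [{k_min}, {k_max}] for (N={N}, K={K}, n={n})"
        )
    numerator = sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, k_max + 1)
    )
    return float(Fraction(numerator, math.comb(N, n)))


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValidationError("p values must lie in [0, 1]")
    if method != "BH":
        raise ValidationError(f"unsupported adjustment method {method!r}")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in adjusted]


def test_all_genes(
    matrix: PresenceMatrix, config: EnrichmentConfig | None = None
) -> list[EnrichmentResult]:
    """Run the enrichment test for every catalog KO detected at least once.

    BH adjustment is applied across exactly the tested set (all n >= 1
    genes), then the dual threshold is evaluated.  Results are sorted by
    adjusted p ascending, ties broken by KO id.  A degenerate host partition
    (K = 0 or K = N) warns and yields all-p=1 results rather than failing.
    """
    config = config or EnrichmentConfig()
    N, K = matrix.N, matrix.K
    if N > 0 and (K == 0 or K == N):
        warnings.warn(
            f"degenerate host partition (K={K}, N={N}): every upper-tail "
            "probability is 1 and no gene can be enriched",
            stacklevel=2,
        )

    tested: list[tuple[str, int, int]] = []
    for ko in matrix.genes:
        n, k = matrix.gene_counts(ko)
        if n >= 1:
            tested.append((ko, n, k))

    p_raw = [hypergeom_upper_tail(k, N, K, n) for _, n, k in tested]
    p_adj = adjust_pvalues(p_raw, method=config.adjust_method)

    results = [
        EnrichmentResult(
            ko_id=ko,
            n=n,
            k=k,
            K=K,
            N=N,
            p_raw=p,
            p_adj=q,
            neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            enriched=(q < config.alpha_adj and n > config.min_n),
        )
        for (ko, n, k), p, q in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.ko_id))
    return results


def results_to_frame(
    results: Sequence[EnrichmentResult],
    catalog: Sequence[GeneCatalogEntry] | None = None,
) -> pd.DataFrame:
    """Tabulate results; with a catalog, gene names and the sporulation flag
    are joined in (first locus per KO)."""
    frame = pd.DataFrame(
        {
            "ko_id": [r.ko_id for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "neg_log10_p": [round(r.neg_log10_p, 6) for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
    if catalog is not None:
        first: dict[str, GeneCatalogEntry] = {}
        for entry in catalog:
            first.setdefault(entry.ko_id, entry)
        frame.insert(
            1, "gene_name", [getattr(first.get(k), "gene_name", "") for k in frame.ko_id]
        )
        frame.insert(
            2,
            "is_sporulation",
            [getattr(first.get(k), "is_sporulation", False) for k in frame.ko_id],
        )
    return frame


def plot_volcano(
    results: Sequence[EnrichmentResult],
    path,
    config: EnrichmentConfig | None = None,
) -> None:
    """Scatter of detections (x) vs -log10 raw p (y) with threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "sporeamg"  # deterministic SVG ids

    config = config or EnrichmentConfig()
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [r.n for r in results]
    ys = [r.neg_log10_p for r in results]
    colors = ["#6a51a3" if r.enriched else "#9e9e9e" for r in results]
    ax.scatter(xs, ys, c=colors, s=14, alpha=0.8, edgecolors="none")
    ax.axhline(-math.log10(config.alpha_adj), ls="--", lw=0.8, c="k")
    ax.axvline(config.min_n, ls="--", lw=0.8, c="k")
    ax.set_xlabel("number of phages with the gene (n)")
    ax.set_ylabel(r"$-\log_{10}$ hypergeometric $P$")
    fig.tight_layout()
    # strip the creation date so outputs are byte-reproducible
    metadata = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, metadata=metadata)
    plt.close(fig)
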