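"""Gene-length-bias-aware GO overrepresentation.

The expressed-gene universe is every gene with a count of at least 2 in
any sample.  Terms with fewer than 5 annotated genes in the universe are
dropped.  Each remaining term is tested with the upper tail of the
Wallenius noncentral hypergeometric distribution, whose odds parameter is
derived from a monotone estimate of P(gene in interest set | gene length):
per-gene weights are binned means of interest-set membership over gene
length, smoothed by isotonic regression (a simpler, monotone stand-in for
a spline probability-weighting function), and the term odds is the odds
ratio of the mean weight inside vs outside the term.  Terms are flagged
overrepresented at raw p < alpha (no multiple-testing correction by
default; Benjamini-Hochberg is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .formats import CountMatrix, JellyseqError


class GoError(JellyseqError):
    pass


@dataclass
class GoConfig:
    min_expressed_count: int = 2
    min_term_size: int = 5
    alpha: float = 0.05
    bias: Literal["length", "none"] = "length"
    n_bins: int = 10
    epsilon: float = 1e-3
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if min(self.min_expressed_count, self.min_term_size) < 0 or self.alpha <= 0:
            raise GoError("thresholds must be positive")


def build_universe(matrix: CountMatrix, config: GoConfig | None = None) -> set[str]:
    """Expressed-gene universe: count >= threshold in at least one sample."""
    config = config or GoConfig()
    mask = (matrix.counts >= config.min_expressed_count).any(axis=1)
    universe = set(matrix.counts.index[mask])
    if not universe:
        raise GoError("no gene passes the expression threshold")
    return universe


def length_bias_weights(
    universe: Sequence[str],
    interest_set: set[str],
    gene_lengths: Mapping[str, float],
    n_bins: int = 10,
    epsilon: float = 1e-3,
) -> dict[str, float]:
    """Monotone estimate of P(in interest set | gene length) per gene.

    Genes are sorted by length and split into equal-occupancy bins; the
    per-bin interest fraction is smoothed with isotonic regression against
    the bin mean length and evaluated at each gene's length, then clipped
    to (epsilon, 1 - epsilon).
    """
    genes = list(universe)
    lengths = np.array([float(gene_lengths[g]) for g in genes])
    if (lengths <= 0).any():
        raise GoError("gene lengths must be positive")
    member = np.array([g in interest_set for g in genes], dtype=float)
    if member.all() or not member.any():
        warnings.warn("interest set covers all or none of the universe; "
                      "falling back to uniform weights")
        w = float(np.clip(member.mean(), epsilon, 1 - epsilon))
        return {g: w for g in genes}

    order = np.argsort(lengths, kind="stable")
    n_bins = min(n_bins, len(genes))
    bins = np.array_split(order, n_bins)
    bin_x = np.array([lengths[b].mean() for b in bins])
    bin_y = np.array([member[b].mean() for b in bins])
    bin_w = np.array([len(b) for b in bins], dtype=float)
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(bin_x, bin_y, sample_weight=bin_w)
    weights = np.clip(iso.predict(lengths), epsilon, 1 - epsilon)
    return dict(zip(genes, weights))


def term_odds(
    weights: Mapping[str, float], term_genes: set[str], universe: Sequence[str]
) -> float:
    """Wallenius odds of a term: odds ratio of mean weights in vs out."""
    w_in = [weights[g] for g in universe if g in term_genes]
    w_out = [weights[g] for g in universe if g not in term_genes]
    if not w_in or not w_out:
        return 1.0
    m_in, m_out = float(np.mean(w_in)), float(np.mean(w_out))
    return (m_in / (1 - m_in)) / (m_out / (1 - m_out))


def wallenius_pvalue(
    n_annotated: int, n_universe: int, n_set: int, n_hit: int, odds: float = 1.0
) -> float:
    """Upper-tail P(X >= n_hit) under Wallenius noncentral hypergeometric.

    X counts term-annotated genes among n_set draws without replacement
    from a universe of n_universe genes where annotated genes carry weight
    ``odds`` relative to the rest.  With odds = 1 this is the central
    hypergeometric (one-sided Fisher) upper tail.
    """
    if not 0 <= n_annotated <= n_universe or not 0 <= n_set <= n_universe:
        raise GoError("inconsistent universe/term/set sizes")
    if not 0 <= n_hit <= min(n_annotated, n_set):
        raise GoError("n_hit outside its feasible range")
    if odds <= 0:
        raise GoError("odds must be positive")
    if n_hit == 0:
        return 1.0
    dist = nchypergeom_wallenius(M=n_universe, n=n_annotated, N=n_set, odds=odds)
    p = float(dist.sf(n_hit - 1))
    if not np.isfinite(p) or p <= 0:
        # fall back to the central tail at extreme odds/underflow
        p = float(hypergeom(n_universe, n_annotated, n_set).sf(n_hit - 1))
    return float(np.clip(p, np.nextafter(0, 1), 1.0))


def run_go(
    interest_set: set[str],
    universe: set[str],
    gene2go: Mapping[str, set[str]],
    gene_lengths: Mapping[str, float],
    config: GoConfig | None = None,
) -> pd.DataFrame:
    """Test every sufficiently large GO term for overrepresentation.

    ``gene2go`` maps term -> annotated genes.  Mappings are restricted to
    the universe; terms with fewer than ``min_term_size`` genes in the
    universe are dropped.  Returns a DataFrame sorted by p with columns
    term_id, n_annotated, n_in_set, expected, odds, p_over and the
    overrepresentation flag.
    """
    config = config or GoConfig()
    interest = interest_set & universe
    universe_list = sorted(universe)
    n_universe, n_set = len(universe_list), len(interest)

    if config.bias == "length":
        weights = length_bias_weights(
            universe_list, interest, gene_lengths,
            n_bins=config.n_bins, epsilon=config.epsilon,
        )
    else:
        weights = None

    rows = []
    for term, genes in gene2go.items():
        members = set(genes) & universe
        if len(members) < config.min_term_size:
            continue
        n_annotated = len(members)
        n_hit = len(members & interest)
        odds = 1.0 if weights is None else term_odds(weights, members, universe_list)
        p = wallenius_pvalue(n_annotated, n_universe, n_set, n_hit, odds)
        rows.append(
            {
                "term_id": term,
                "n_annotated": n_annotated,
                "n_in_set": n_hit,
                "expected": n_set * n_annotated / n_universe,
                "odds": odds,
                "p_over": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "n_annotated", "n_in_set", "expected", "odds", "p_over"],
    )
    if len(result):
        result = result.sort_values("p_over", kind="stable").reset_index(drop=True)
        if config.bh_correction:
            m = len(result)
            ranked = result["p_over"].to_numpy() * m / (np.arange(m) + 1)
            result["p_adjusted"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(0, 1)
            result["flag_overrepresented"] = result["p_adjusted"] < config.alpha
        else:
            result["flag_overrepresented"] = result["p_over"] < config.alpha
    else:
        result["flag_overrepresented"] = pd.Series(dtype=bool)
    return result
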