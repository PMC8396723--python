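"""Tajima's D neutrality screening over per-gene alignments.

D contrasts mean pairwise diversity (pi) with the number of segregating
sites scaled by Watterson's constant; under neutrality its expectation
is near zero.  Following the source study's convention, a significantly
negative D is labelled "positive" selection and a significantly positive
D "purifying".  (The statistic also responds to demography — expansion
mimics negative D, structure positive D — so these labels are a screen,
not proof of selection; see the methods note.)

Significance uses the beta-distribution approximation of D's null
density (Tajima 1989), with the normal approximation reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import Alignment

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class TajimaResult:
    gene: str
    n: int
    S: int
    pi: float
    D: float
    p_beta: float
    p_normal: float
    selection_class: str  # purifying / positive / neutral / not computed


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def segregating_sites(aln: Alignment) -> int:
    """Segregating sites over complete columns (no gap/N anywhere)."""
    mat = aln.matrix
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])
    complete = counts.sum(axis=0) == aln.n_rows
    k = (counts > 0).sum(axis=0)
    return int(((k >= 2) & complete).sum())


def mean_pairwise_differences(aln: Alignment) -> float:
    """Average pairwise difference count with pairwise deletion of
    gap/N sites."""
    mat = aln.matrix
    valid = np.zeros(mat.shape, dtype=bool)
    for b in _BASES:
        valid |= mat == b
    n = aln.n_rows
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total += int(((mat[i] != mat[j]) & both).sum())
            pairs += 1
    return total / pairs if pairs else 0.0


def tajimas_d(aln: Alignment, gene: str = "") -> TajimaResult:
    """Tajima's D with beta- and normal-approximation p-values.

    With no segregating sites the statistic is undefined and the result
    is classed "not computed" (no exception).  Requires n >= 4.
    """
    n = aln.n_rows
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    S = segregating_sites(aln)
    pi = mean_pairwise_differences(aln)
    if S == 0:
        return TajimaResult(gene, n, 0, pi, math.nan, math.nan, math.nan, "not computed")
    k = _tajima_constants(n)
    D = (pi - S / k["a1"]) / math.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    # beta approximation of the null density on [Dmin, Dmax]
    dmin = (2.0 / n - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    dmax = ((n + 1) / (2.0 * n) - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    tmp1 = 1.0 + dmin * dmax
    tmp2 = dmax - dmin
    alpha = -tmp1 * dmax / tmp2
    beta = tmp1 * dmin / tmp2
    x = (D - dmin) / tmp2
    p_beta = float(stats.beta.cdf(x, beta, alpha))
    p_beta = 2 * (1 - p_beta) if p_beta > 0.5 else 2 * p_beta
    p_normal = float(2 * stats.norm.sf(abs(D)))
    if p_beta <= 0.05:
        selection_class = "positive" if D < 0 else "purifying"
    else:
        selection_class = "neutral"
    return TajimaResult(gene, n, S, pi, D, p_beta, p_normal, selection_class)


def screen_genes(
    per_gene_alignments: dict[str, Alignment],
) -> tuple[list[TajimaResult], dict[str, int]]:
    """Tajima's D for every gene plus summary counts by selection class."""
    results = [tajimas_d(aln, gene=g) for g, aln in sorted(per_gene_alignments.items())]
    summary = {"purifying": 0, "positive": 0, "neutral": 0, "not computed": 0}
    for res in results:
        summary[res.selection_class] += 1
    return results, summary
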