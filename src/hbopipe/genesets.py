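"""Gene-list overlap and gene-set enrichment statistics.

Covers the downstream comparative layer of the transcriptomic arm:

* representation factor + exact hypergeometric tail for the overlap of two
  DEG lists against a background universe,
* Venn partitioning of 2-3 gene lists,
* over-representation analysis of a query list against a GMT collection
  (hypergeometric p, Benjamini-Hochberg q),
* pre-ranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum,
  gene-set-permutation NES, permutation p and FDR).

The representation factor RF = x * N / (n1 * n2) is the observed overlap x
of lists of sizes n1 and n2 over the overlap expected by chance in a
background of N genes; RF > 1 means greater-than-random co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# overlap statistics


@dataclass
class OverlapResult:
    n1: int
    n2: int
    x: int
    N: int
    rf: float
    p: float


def hypergeom_tail(x: int, n1: int, n2: int, N: int) -> float:
    """Exact upper tail P(X >= x) for the overlap of two random lists.

    X is hypergeometric: draw n2 genes from a universe of N containing n1
    marked genes; X counts marked draws.  Computed in log space by scipy,
    stable for large N.
    """
    _check_overlap(x, n1, n2, N)
    if x == 0:
        return 1.0
    return float(_st.hypergeom.sf(x - 1, N, n1, n2))


def representation_factor(x: int, n1: int, n2: int, N: int) -> OverlapResult:
    """Observed/expected overlap ratio with its hypergeometric tail p."""
    _check_overlap(x, n1, n2, N)
    rf = x * N / (n1 * n2)
    return OverlapResult(n1=n1, n2=n2, x=x, N=N, rf=rf, p=hypergeom_tail(x, n1, n2, N))


def _check_overlap(x: int, n1: int, n2: int, N: int):
    if min(x, n1, n2) < 0 or N <= 0:
        raise ValueError("sizes must be non-negative and N positive")
    if n1 == 0 or n2 == 0:
        raise ValueError("list sizes n1, n2 must be positive")
    if x > min(n1, n2):
        raise ValueError(f"overlap x={x} exceeds min(n1, n2)={min(n1, n2)}")
    if n1 + n2 - x > N:
        raise ValueError(f"lists of {n1} and {n2} with overlap {x} cannot fit in N={N}")


def venn_partition(*sets: set | list) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 gene lists.

    Keys are binary membership patterns ("10", "01", "11" for two sets;
    "100" ... "111" for three), value = number of genes in exactly that
    combination.  Region counts sum to the union size.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_partition takes 2 or 3 sets")
    ss = [set(s) for s in sets]
    universe = set().union(*ss)
    counts: dict[str, int] = {}
    k = len(ss)
    for code in range(1, 2**k):
        pattern = format(code, f"0{k}b")
        counts[pattern] = 0
    for g in universe:
        pattern = "".join("1" if g in s else "0" for s in ss)
        counts[pattern] += 1
    return counts


# ---------------------------------------------------------------------------
# GMT collections and over-representation


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with an optional category tag."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {k: set(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, category: str = "") -> GeneSetCollection:
    """Read a tab-delimited GMT file (name, description, member genes...)."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = set(g for g in parts[2:] if g)
        desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc, category=category)


def write_gmt(collection: GeneSetCollection, path: str | Path):
    lines = []
    for name, members in collection.sets.items():
        d = collection.descriptions.get(name, "")
        lines.append("\t".join([name, d] + sorted(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_enrichment(
    genes: list[str],
    background: list[str],
    collection: GeneSetCollection,
    q_threshold: float | None = None,
) -> pd.DataFrame:
    """Over-representation of a query list in each set of a collection.

    Per set: overlap k with the query, expected overlap under random draws,
    hypergeometric upper-tail p, Benjamini-Hochberg q over all sets tested.
    Sets are intersected with the background universe first.  Sorted by
    (q, p); optionally truncated at ``q < q_threshold``.
    """
    bg = set(background)
    query = set(genes)
    outside = sorted(query - bg)
    if outside:
        raise ValueError(f"query genes outside background: {outside[:10]}")
    if not query:
        return pd.DataFrame(columns=["set", "size", "k", "expected", "p", "q"]).set_index("set")
    N, n = len(bg), len(query)
    rows = []
    for name, members in collection.sets.items():
        m = len(members & bg)
        if m == 0:
            continue
        k = len(members & query)
        p = float(_st.hypergeom.sf(k - 1, N, m, n)) if k > 0 else 1.0
        rows.append((name, m, k, m * n / N, p))
    if not rows:
        return pd.DataFrame(columns=["set", "size", "k", "expected", "p", "q"]).set_index("set")
    df = pd.DataFrame(rows, columns=["set", "size", "k", "expected", "p"]).set_index("set")
    _, q, *_ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df = df.sort_values(["q", "p"])
    if q_threshold is not None:
        df = df[df["q"] < q_threshold]
    return df


# ---------------------------------------------------------------------------
# pre-ranked enrichment (weighted KS running sum)


def rank_genes(deg_table: pd.DataFrame) -> pd.Series:
    """Ranking metric from a DEG table: sign(log2 FC) * (-log10 p).

    Returns a Series (gene -> score) sorted descending; ties broken by
    ascending gene id so the ranking is deterministic.
    """
    if not {"log2_fc", "p"}.issubset(deg_table.columns):
        raise ValueError("deg_table needs 'log2_fc' and 'p' columns")
    p = np.maximum(deg_table["p"].to_numpy(float), 1e-300)
    score = np.sign(deg_table["log2_fc"].to_numpy(float)) * (-np.log10(p))
    s = pd.Series(score, index=deg_table.index, name="score")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return s.loc[order]


def preranked_es(ranked: pd.Series, geneset: set[str], weight: float = 1.0) -> float:
    """Enrichment score of one set against a ranked list.

    Weighted Kolmogorov-Smirnov running sum: walking down the ranking, a
    set member ("hit") increments by |score|^weight normalized over hits, a
    non-member decrements by 1/(N - Nh).  The ES is the running sum's
    maximum-magnitude deviation from zero (signed); with weight 0 this is
    the classical KS statistic on ranks.
    """
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(geneset))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh == genes.size:
        raise ValueError("gene set covers the whole ranked list")
    return float(_es_from_positions(np.flatnonzero(hit)[None, :],
                                    np.abs(ranked.to_numpy(float)) ** weight,
                                    genes.size)[0])


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Signed max-deviation ES for each row of hit positions.

    ``pos``: (P, k) sorted hit positions; ``w``: per-gene hit weights
    (|score|^weight over the full ranking).  Extrema of the piecewise-linear
    running sum occur just after a hit or just before the next, so only hit
    positions matter.
    """
    P, k = pos.shape
    hw = w[pos]
    W = hw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(W > 0, np.cumsum(hw, axis=1) / W, (np.arange(1, k + 1) / k)[None, :])
    d = 1.0 / (n - k)
    j = np.arange(k)[None, :]
    after = cum - (pos - j) * d          # running sum just after hit j
    before = (cum - np.where(W > 0, hw / W, 1.0 / k)) - (pos - j) * d  # just before hit j
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(P), idx]


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Pre-ranked GSEA with gene-set permutation.

    For each set (membership intersected with the ranked list, size within
    [min_size, max_size]) the ES is computed, then normalized against a
    null of ``n_perm`` random same-size gene sets: NES = ES / mean(|null ES|
    of the same sign).  The permutation p is the same-sign null exceedance
    fraction; FDR compares each NES against the pooled normalized null
    across all sets, per the standard gene-set-permutation procedure.
    Null distributions are shared between sets of equal size, and the whole
    computation is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = genes.size
    w = np.abs(ranked.to_numpy(float)) ** weight
    index = {g: i for i, g in enumerate(genes)}

    tested: list[tuple[str, np.ndarray]] = []
    for name, members in collection.sets.items():
        pos = np.sort([index[g] for g in members if g in index])
        if min_size <= pos.size <= max_size and pos.size < n:
            tested.append((name, np.asarray(pos)))
    if not tested:
        return pd.DataFrame(columns=["size", "es", "nes", "p", "fdr"])

    null_cache: dict[int, np.ndarray] = {}

    def null_for(k: int) -> np.ndarray:
        if k not in null_cache:
            r = rng.random((n_perm, n))
            perm_pos = np.sort(np.argpartition(r, k, axis=1)[:, :k], axis=1)
            null_cache[k] = _es_from_positions(perm_pos, w, n)
        return null_cache[k]

    rows = []
    all_null_nes: list[np.ndarray] = []
    for name, pos in tested:
        k = pos.size
        es = float(_es_from_positions(pos[None, :], w, n)[0])
        null = null_for(k)
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
        nes = es / pos_mean if es >= 0 else es / neg_mean
        if es >= 0:
            denom = int((null >= 0).sum())
            count = int((null >= es).sum())
        else:
            denom = int((null < 0).sum())
            count = int((null <= es).sum())
        p = (count + 1) / (denom + 1)
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        all_null_nes.append(null_nes)
        rows.append((name, k, es, float(nes), float(p)))

    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"]).set_index("set")
    pooled = np.concatenate(all_null_nes)
    obs = df["nes"].to_numpy()
    fdr = np.empty(obs.size)
    for i, v in enumerate(obs):
        if v >= 0:
            null_frac = (pooled >= v).sum() / max(1, (pooled >= 0).sum())
            obs_frac = (obs >= v).sum() / max(1, (obs >= 0).sum())
        else:
            null_frac = (pooled <= v).sum() / max(1, (pooled < 0).sum())
            obs_frac = (obs <= v).sum() / max(1, (obs < 0).sum())
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    df["fdr"] = fdr
    return df.sort_values("p")


def oppositely_regulated(
    up_maturation: set[str], up_treat_60: set[str], down_treat_90: set[str]
) -> set[str]:
    """Gene sets (or genes) regulated oppositely by treatment across stages:
    up under treatment at the early stage, down at the late stage, and up
    with maturation itself — the triple intersection."""
    return set(up_maturation) & set(up_treat_60) & set(down_treat_90)
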