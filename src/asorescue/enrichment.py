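"""Over-representation analysis (RichFactor / InTerm) and KSEA-style
inferred kinase activity.

The ORA engine is a one-sided hypergeometric test on user-supplied gene-set
collections, reporting per term the count of selected features in the term
(InTerm), the fraction of the term covered (RichFactor = InTerm / term size),
an exact upper-tail p-value and a BH q-value across tested terms.

Kinase activity is inferred from substrate phosphosite log2 fold-changes
with the KSEA z statistic

    z_k = (mean(lfc over substrates of k) - mean(all lfc)) * sqrt(m_k) / sd(all lfc)

and a two-sided permutation p-value from random same-size site draws. This
is an approximation to dedicated kinase-activity tools and is labelled as
such in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger("asorescue")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    selection: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a selection against gene sets.

    Term membership is intersected with the universe before the term size K
    is computed; only terms overlapping the selection (InTerm >= 1) are
    reported. BH adjustment runs across the tested terms.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    selection_set = set(selection)
    stray = selection_set - universe_set
    if stray:
        raise ValueError(f"selection members outside universe: {sorted(stray)[:10]}")
    N = len(universe_set)
    n = len(selection_set)
    rows = []
    for term, (desc, members) in sorted(gene_sets.items()):
        in_universe = set(members) & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & selection_set)
        if k == 0:
            continue
        rows.append(
            dict(term=term, description=desc, in_term=k, term_size=K,
                 n_selected=n, n_universe=N, rich_factor=k / K,
                 p=hypergeom_upper(k, K, n, N))
        )
    df = pd.DataFrame(
        rows, columns=["term", "description", "in_term", "term_size",
                       "n_selected", "n_universe", "rich_factor", "p"],
    )
    if len(df):
        from .differential import bh_adjust

        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


@dataclass(frozen=True)
class KinaseScore:
    kinase: str
    n_substrates: int
    z: float
    p: float
    direction: str  # "up" or "down"


def read_kinase_map(path) -> dict[str, tuple[str, ...]]:
    """Read a kinase-substrate map TSV with columns kinase, gene, site.

    Substrate sites are keyed ``GENE_site`` to match phosphosite feature ids.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("kinase", "gene", "site"):
        if col not in df.columns:
            raise ValueError(f"kinase map missing column {col!r}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.kinase, []).append(f"{row.gene}_{row.site}")
    return {k: tuple(dict.fromkeys(v)) for k, v in out.items()}


def kinase_activity(
    site_log2fc: pd.Series,
    kinase_substrate_map: Mapping[str, Sequence[str]],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    m_min: int = 3,
) -> pd.DataFrame:
    """KSEA-style kinase activity scores with permutation p-values.

    ``site_log2fc`` maps phosphosite ids to log2 fold-changes of one
    contrast; ``kinase_substrate_map`` maps kinase -> substrate site ids.
    Mapped sites absent from the data are dropped with a warning; kinases
    left with fewer than ``m_min`` substrates are skipped. Permutation
    p-values are two-sided with add-one correction, (b + 1) / (n_perm + 1),
    from ``n_perm`` random draws of the same substrate count; deterministic
    given ``seed``.
    """
    lfc = site_log2fc.dropna()
    values = lfc.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 quantified sites")
    mean_all = values.mean()
    sd_all = values.std(ddof=1)
    if sd_all == 0:
        raise ValueError("site log2FCs are constant; scores undefined")
    index = {s: i for i, s in enumerate(lfc.index)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for kinase in sorted(kinase_substrate_map):
        sites = kinase_substrate_map[kinase]
        present = [index[s] for s in sites if s in index]
        dropped = len(sites) - len(present)
        if dropped:
            logger.warning("kinase %s: %d substrate site(s) not quantified",
                           kinase, dropped)
        if len(present) < m_min:
            logger.warning("kinase %s skipped: %d substrate(s) < m_min=%d",
                           kinase, len(present), m_min)
            continue
        kept.append((kinase, np.asarray(present)))

    # shared null per substrate count: draw n_perm random site sets of size m
    null_by_m: dict[int, np.ndarray] = {}
    for m in sorted({len(idx) for _, idx in kept}):
        means = np.empty(n_perm)
        for b in range(n_perm):
            means[b] = values[rng.choice(len(values), size=m, replace=False)].mean()
        null_by_m[m] = (means - mean_all) * np.sqrt(m) / sd_all

    rows = []
    for kinase, idx in kept:
        m = len(idx)
        z = (values[idx].mean() - mean_all) * np.sqrt(m) / sd_all
        b = int(np.sum(np.abs(null_by_m[m]) >= abs(z)))
        p = (b + 1) / (n_perm + 1)
        rows.append(dict(kinase=kinase, n_substrates=m, z=z, p=p,
                         direction="up" if z >= 0 else "down"))
    df = pd.DataFrame(rows, columns=["kinase", "n_substrates", "z", "p", "direction"])
    if len(df):
        df = df.sort_values(["p", "kinase"], kind="mergesort").reset_index(drop=True)
    return df
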