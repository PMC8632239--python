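"""Group statistics over delineation trials.

The three guidance settings are compared per zone code on plane-level
percentages (Kruskal-Wallis with all-pairs Steel-Dwass-Critchlow-Fligner
post-hoc), the plane-level flags (intratumoral, carotid damaged) with
the Fisher-Freeman-Halton exact test on 2 x k count tables, and the
benefit of guidance is summarized as the intraindividual "gain": per
surgeon, the rate of adequate planes under guidance (tumor- and
carotid-guided pooled) minus the unguided rate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .margins import ZONE_CODES

__all__ = [
    "kruskal_wallis",
    "steel_dwass_critchlow_fligner",
    "fisher_exact_rxc",
    "GroupComparison",
    "compare_groups",
    "GainResult",
    "compute_gain",
]


def kruskal_wallis(groups, method: str = "chisq", n_perm: int = 100_000, seed: int = 0):
    """Tie-corrected Kruskal-Wallis H with a chi-square or permutation p.

    ``method='chisq'`` refers H to the chi-square distribution with k-1
    degrees of freedom (the usual large-sample reference);
    ``method='permutation'`` estimates ``P(H* >= H)`` over ``n_perm``
    random relabelings, which is preferable for small groups where the
    chi-square approximation is off by more than Monte-Carlo error.
    Degenerate all-identical data returns (0, 1) rather than raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    if method == "chisq":
        return float(H), float(p)
    if method != "permutation":
        raise ValueError("method must be 'chisq' or 'permutation'")

    sizes = [len(g) for g in groups]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    ranks = sps.rankdata(pooled)
    N = len(pooled)

    def h_of(rank_matrix):
        # H from realized ranks; exact under ties
        ss = np.zeros(rank_matrix.shape[0])
        for i, n_i in enumerate(sizes):
            block = rank_matrix[:, offsets[i] : offsets[i + 1]]
            ss += block.sum(axis=1) ** 2 / n_i
        mean_r = (N + 1) / 2.0
        var_r = np.sum((ranks - mean_r) ** 2) / (N - 1)
        return (ss - N * mean_r**2) / var_r

    rng = np.random.default_rng(seed)
    h_obs = h_of(ranks[None, :])[0]
    count = 0
    chunk = 20_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
        count += int(np.sum(h_of(perm) >= h_obs - 1e-12))
        done += m
    return float(H), float((count + 1) / (n_perm + 1))


def _pair_z(x, y):
    """Tie-corrected standardized rank-sum statistic for one pair."""
    n1, n2 = len(x), len(y)
    N = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    W = ranks[:n1].sum()
    E = n1 * (N + 1) / 2.0
    # variance from the realized ranks (absorbs ties exactly)
    V = n1 * n2 / (N * (N - 1.0)) * (np.sum(ranks**2) - N * (N + 1.0) ** 2 / 4.0)
    if V <= 0:
        return 0.0
    return (W - E) / math.sqrt(V)


def steel_dwass_critchlow_fligner(groups, method: str = "asymptotic"):
    """All-pairs nonparametric post-hoc comparison after Kruskal-Wallis.

    For each pair of groups the two-sample rank statistic is computed on
    that pair alone and referred to the studentized-range distribution
    with k groups (the Steel-Dwass all-pairs procedure):
    ``p = P(q_{k,inf} >= sqrt(2) |z|)``.

    ``method='exact'`` replaces the studentized-range reference by full
    enumeration of the permutation distribution of the *maximum*
    pairwise statistic over all relabelings of the pooled sample (the
    single-step max-T adjustment the asymptotic reference approximates);
    it is feasible only for small samples.

    Returns the symmetric (k, k) p-value matrix with unit diagonal.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("post-hoc all-pairs comparison needs >= 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")

    zobs = {}
    for i, j in itertools.combinations(range(k), 2):
        zobs[(i, j)] = _pair_z(groups[i], groups[j])

    P = np.eye(k)
    np.fill_diagonal(P, 1.0)
    if method == "asymptotic":
        for (i, j), z in zobs.items():
            p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(z), k, np.inf))
            P[i, j] = P[j, i] = min(p, 1.0)
        return P
    if method != "exact":
        raise ValueError("method must be 'asymptotic' or 'exact'")

    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n_alloc = math.factorial(sum(sizes)) // math.prod(math.factorial(s) for s in sizes)
    if n_alloc > 200_000:
        raise ValueError(f"exact enumeration infeasible: {n_alloc} allocations")

    idx_all = list(range(len(pooled)))
    alloc = np.array(
        [[i for block in combo for i in block] for combo in _multiset_partitions(idx_all, sizes)]
    )
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    max_stats = np.zeros(len(alloc))
    for i, j in itertools.combinations(range(k), 2):
        cols = np.r_[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]]
        vals = pooled[alloc[:, cols]]  # (n_alloc, n_i + n_j)
        n1, n2 = sizes[i], sizes[j]
        N = n1 + n2
        ranks = sps.rankdata(vals, axis=1)
        W = ranks[:, :n1].sum(axis=1)
        E = n1 * (N + 1) / 2.0
        V = n1 * n2 / (N * (N - 1.0)) * (np.sum(ranks**2, axis=1) - N * (N + 1.0) ** 2 / 4.0)
        z = np.where(V > 0, (W - E) / np.sqrt(np.maximum(V, 1e-300)), 0.0)
        max_stats = np.maximum(max_stats, np.abs(z))
    for (i, j), z in zobs.items():
        p = float(np.mean(max_stats >= abs(z) - 1e-12))
        P[i, j] = P[j, i] = p
    return P


def _multiset_partitions(indices, sizes):
    """All ordered partitions of ``indices`` into blocks of given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for head in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in head]
        for tail in _multiset_partitions(rest, sizes[1:]):
            yield (head,) + tail


def fisher_exact_rxc(table) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    Sums the multivariate hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of
    the observed table.  Degenerate margins (a zero row or column)
    return p = 1.
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return 1.0

    lf = [math.lgamma(n + 1) for n in range(int(T.sum()) + 1)]

    def log_prob(cells):
        return (
            sum(lf[r] for r in row)
            + sum(lf[c] for c in col)
            - lf[int(T.sum())]
            - sum(lf[int(v)] for v in cells)
        )

    obs = log_prob(T.ravel())
    total = 0.0
    # enumerate all tables with the given margins, row by row
    def rec(r, remaining_col, acc):
        nonlocal total
        if r == len(row) - 1:
            cells = acc + list(remaining_col)
            lp = log_prob(cells)
            if lp <= obs + 1e-9:
                total += math.exp(lp)
            return
        for combo in _compositions(int(row[r]), remaining_col):
            rec(r + 1, remaining_col - np.array(combo), acc + list(combo))

    rec(0, col.copy(), [])
    return float(min(total, 1.0))


def _compositions(total, caps):
    """All nonnegative integer vectors summing to ``total`` with v_i <= caps_i."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for v in range(min(total, int(caps[0])) + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield (v,) + rest


def _as_frame(records):
    """Accept either TrialRecord objects or an exported records table."""
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        return records
    from .behavior import records_to_frame

    return records_to_frame(records)


@dataclass
class GroupComparison:
    """Zone-by-setting comparison of the guidance settings."""

    settings: tuple
    zone_means: dict  # code -> {setting: mean percent}
    zone_tests: dict  # code -> {"H", "p", "posthoc" (k x k array)}
    flag_tables: dict  # flag -> {"table": 2 x k counts, "p": exact p}
    n_records: dict  # setting -> count
    alpha: float = 0.05

    def to_markdown(self) -> str:
        lines = [
            "| Zone | " + " | ".join(self.settings) + " | p |",
            "|" + "---|" * (len(self.settings) + 2),
        ]
        for code in ZONE_CODES:
            means = self.zone_means[code]
            p = self.zone_tests[code]["p"]
            cells = " | ".join(f"{means[s]:.1f}" for s in self.settings)
            lines.append(f"| {code} | {cells} | {p:.4g} |")
        return "\n".join(lines)


def compare_groups(records) -> GroupComparison:
    """Aggregate trial records into the headline zone-by-setting comparison.

    Per zone code: mean plane-level percentage per setting, a
    Kruskal-Wallis test across settings on those percentages, and the
    Steel-Dwass all-pairs post-hoc matrix.  Per plane-level flag
    (intratumoral, carotid damaged): a 2 x k count table with the
    Freeman-Halton exact p.  Settings with zero records are excluded
    with a warning.
    """
    from .behavior import SETTINGS

    df = _as_frame(records)
    present = [s for s in SETTINGS if (df.setting == s).any()]
    missing = [s for s in SETTINGS if s not in present]
    if missing:
        warnings.warn(f"settings with zero records excluded: {missing}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("need records from at least two settings")

    zone_means, zone_tests = {}, {}
    for code in ZONE_CODES:
        col = f"frac_{code}"
        groups = [df.loc[df.setting == s, col].to_numpy() * 100.0 for s in present]
        zone_means[code] = {s: float(g.mean()) for s, g in zip(present, groups)}
        H, p = kruskal_wallis(groups)
        posthoc = None
        if len(present) >= 3 and all(len(g) >= 2 for g in groups):
            posthoc = steel_dwass_critchlow_fligner(groups)
        zone_tests[code] = {"H": H, "p": p, "posthoc": posthoc}

    flag_tables = {}
    for flag in ("intratumoral", "ica_damaged"):
        pos = np.array([int(df.loc[df.setting == s, flag].sum()) for s in present])
        tot = np.array([int((df.setting == s).sum()) for s in present])
        table = np.stack([pos, tot - pos])
        flag_tables[flag] = {"table": table, "p": fisher_exact_rxc(table)}

    return GroupComparison(
        settings=tuple(present),
        zone_means=zone_means,
        zone_tests=zone_tests,
        flag_tables=flag_tables,
        n_records={s: int((df.setting == s).sum()) for s in present},
    )


@dataclass
class GainResult:
    """Intraindividual improvement from guidance, per surgeon and pooled."""

    per_surgeon: dict  # surgeon_id -> {"clear_margin": %, "carotid_spared": %}
    mean_clear_margin: float
    mean_carotid_spared: float
    range_clear_margin: tuple
    range_carotid_spared: tuple


def compute_gain(records) -> GainResult:
    """Guided (pooled) minus unguided rates of adequate planes.

    Per surgeon: the difference, in percentage points, of the rate of
    clear-margin planes (no point inside the tumor) and of
    carotid-spared planes (no point inside the vessel), between the
    pooled tumor-/carotid-guided records and the unguided ones.
    Surgeons missing either side are excluded with a warning.
    """
    df = _as_frame(records).copy()
    df["clear_margin"] = ~df.intratumoral
    df["carotid_spared"] = ~df.ica_damaged
    df["guided"] = df.setting != "unguided"

    per_surgeon = {}
    for sid, sub in df.groupby("surgeon_id"):
        if not (sub.guided.any() and (~sub.guided).any()):
            warnings.warn(f"surgeon {sid} lacks a setting; excluded from gain", stacklevel=2)
            continue
        g = sub[sub.guided]
        u = sub[~sub.guided]
        per_surgeon[int(sid)] = {
            "clear_margin": 100.0 * (g.clear_margin.mean() - u.clear_margin.mean()),
            "carotid_spared": 100.0 * (g.carotid_spared.mean() - u.carotid_spared.mean()),
        }
    if not per_surgeon:
        raise ValueError("no surgeon has both guided and unguided records")
    cm = np.array([v["clear_margin"] for v in per_surgeon.values()])
    cs = np.array([v["carotid_spared"] for v in per_surgeon.values()])
    return GainResult(
        per_surgeon=per_surgeon,
        mean_clear_margin=float(cm.mean()),
        mean_carotid_spared=float(cs.mean()),
        range_clear_margin=(float(cm.min()), float(cm.max())),
        range_carotid_spared=(float(cs.min()), float(cs.max())),
    )
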