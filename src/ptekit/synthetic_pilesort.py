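"""Planted-theme pile-sort generator.

Real pile-sort datasets from participatory theme elicitation panels are
small and rarely shared, so the toolkit ships a generative stand-in: N
quotes carry K latent themes, and each of S sorters reproduces the themes
as piles, imperfectly.  Three kinds of sorter-level imperfection are
modelled, each observed in practice:

* **merging** — a sorter lumps two adjacent themes into one pile
  (probability ``p_merge`` per adjacent theme pair);
* **splitting** — a sorter divides a theme into two piles
  (probability ``p_split`` per unmerged theme);
* **misassignment noise** — each quote independently lands in a uniformly
  random pile of that sorter with probability ``noise``, instead of its
  theme's pile.

At ``noise = 0`` every sorter reproduces the planted themes exactly (when
merging and splitting are off), so the co-occurrence network is K disjoint
uniform cliques; at ``noise = 1`` assignment is uniform over the sorter's
piles, which makes within-theme and cross-theme co-sorting exactly
equidistributed — the no-signal null.

Defaults mirror a typical panel study: 49 quotes, 9 sorters, 6 themes,
with merge/split rates that put per-sorter pile counts in the 3-12 range
commonly seen in sorting tasks.

Randomness is fully reproducible: one root seed, with an independent
sub-stream per sorter derived from (seed, sorter index), so adding a
sorter never perturbs the piles of existing sorters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .community import best_partition, girvan_newman, greedy_modularity
from .cooccurrence import build_network
from .errors import ValidationError
from .partitions import Partition
from .partition_tools import adjusted_rand
from .pilesort_data import Quote, SortRecord, SortingStudy

__all__ = [
    "SyntheticSpec",
    "SyntheticStudy",
    "RecoverySummary",
    "generate",
    "recovery_experiment",
    "ALGORITHMS",
]

ALGORITHMS = {
    "girvan_newman": girvan_newman,
    "greedy_modularity": greedy_modularity,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-theme generator.

    Attributes
    ----------
    n_quotes : int
        N, number of quotes (default 49, a typical panel's quote list).
    n_themes : int
        K, number of planted themes; quotes are assigned round-robin.
    n_sorters : int
        S, panel size (default 9).
    noise : float
        Per-(sorter, quote) misassignment probability in [0, 1].
    p_merge : float
        Probability a sorter merges each adjacent theme pair into one pile.
    p_split : float
        Probability a sorter splits each (unmerged) theme into two piles.
    seed : int
        Root seed; the whole study is a deterministic function of the spec.
    """

    n_quotes: int = 49
    n_themes: int = 6
    n_sorters: int = 9
    noise: float = 0.1
    p_merge: float = 0.2
    p_split: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_quotes < 1 or self.n_sorters < 1 or self.n_themes < 1:
            raise ValidationError("n_quotes, n_themes and n_sorters must be >= 1")
        if self.n_themes > self.n_quotes:
            raise ValidationError("n_themes may not exceed n_quotes")
        for name in ("noise", "p_merge", "p_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study together with its planted ground truth."""

    study: SortingStudy
    planted: Partition
    spec: SyntheticSpec


def _quote_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"q{i + 1:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> SyntheticStudy:
    """Draw one pile-sort study from the planted-theme model.

    Per sorter, the random draws happen in a fixed order (merge decisions,
    split decisions, per-quote sub-pile and noise draws) from a sub-stream
    seeded by (root seed, sorter index), so output is reproducible and
    stable under changes to ``n_sorters``.
    """
    n, k, s = spec.n_quotes, spec.n_themes, spec.n_sorters
    ids = _quote_ids(n)
    theme_of = {qid: i % k for i, qid in enumerate(ids)}
    planted = Partition({qid: f"T{theme_of[qid] + 1}" for qid in ids})

    records: list[SortRecord] = []
    for s_idx in range(s):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, s_idx)))
        sorter = f"s{s_idx + 1:02d}"

        # merge adjacent theme pairs into shared piles (chains allowed)
        merge = rng.random(max(k - 1, 0)) < spec.p_merge
        pile_of_theme = list(range(k))
        for t in range(k - 1):
            if merge[t]:
                tgt = pile_of_theme[t]
                pile_of_theme[t + 1] = tgt
        merged_groups = {pile_of_theme[t] for t in range(k) if pile_of_theme.count(pile_of_theme[t]) > 1}

        # split unmerged themes into two sub-piles
        split = rng.random(k) < spec.p_split
        home_pile: dict[str, str] = {}
        for qid in ids:
            t = theme_of[qid]
            base = pile_of_theme[t]
            if split[t] and base not in merged_groups:
                half = "a" if rng.random() < 0.5 else "b"
                home_pile[qid] = f"P{base + 1}{half}"
            else:
                home_pile[qid] = f"P{base + 1}"

        piles = sorted(set(home_pile.values()))
        for qid in ids:
            if spec.noise > 0 and rng.random() < spec.noise:
                pile = piles[rng.integers(len(piles))]
            else:
                pile = home_pile[qid]
            records.append(SortRecord(sorter, qid, pile))

    quotes = [Quote(qid, text=f"Synthetic excerpt {qid}.") for qid in ids]
    return SyntheticStudy(
        study=SortingStudy(records, quotes=quotes), planted=planted, spec=spec
    )


# ---------------------------------------------------------------------------
# Recovery experiments


@dataclass(frozen=True)
class RecoverySummary:
    """Planted-partition recovery across seeded replicates."""

    algorithm: str
    spec: SyntheticSpec
    replicates: int
    aris: tuple[float, ...]

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.aris))

    @property
    def sd_ari(self) -> float:
        if len(self.aris) < 2:
            return 0.0
        return float(np.std(self.aris, ddof=1))


def recovery_experiment(
    spec: SyntheticSpec, algorithm: str, replicates: int = 30
) -> RecoverySummary:
    """How well an algorithm recovers the planted themes.

    Runs ``replicates`` independent studies (seeds ``spec.seed + r``),
    detects communities on each co-occurrence network, and measures the
    adjusted Rand index between the algorithm's best partition and the
    planted one.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    run = ALGORITHMS[algorithm]
    aris = []
    for r in range(replicates):
        syn = generate(replace(spec, seed=spec.seed + r))
        net = build_network(syn.study)
        part = best_partition(run(net))
        aris.append(adjusted_rand(part, syn.planted))
    return RecoverySummary(
        algorithm=algorithm, spec=spec, replicates=replicates, aris=tuple(aris)
    )
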