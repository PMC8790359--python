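"""Synthetic two-corpus generator with planted prevalence and cluster structure.

Real health-mention corpora are heavy-tailed: a handful of conditions are
mentioned enormously often while most appear once or twice. This module
emulates that regime with a Zipf frequency law over a synthetic condition
vocabulary, and plants known structure on top of it so the downstream
classifier and network builder can be scored against ground truth:

* a five-way prevalence structure — conditions shared equally between the
  "waking" mention corpus and the "dream" report corpus, conditions
  exclusive to one corpus, and conditions enriched in one corpus (their
  sampling weight in the other corpus is taken at a Zipf rank displaced by
  ``rank_shift`` positions, which displaces their observed frequency rank
  by roughly that amount while preserving the marginal Zipf shape);
* planted co-occurrence clusters in the dream reports — each report picks a
  seed condition, then fills the rest of its slots from the seed's cluster
  with probability ``within_cluster_prob`` and from the whole vocabulary
  otherwise.

All randomness flows from the spec seed; identical specs produce
bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import csv
import numpy as np

from .ingest import MentionRecord, ReportConditionSet

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CLASS_LABELS",
    "generate_vocabulary",
    "generate_corpora",
    "generate_null_reports",
    "write_ground_truth_tsv",
]

#: Planted prevalence class labels.
CLASS_LABELS = ("EQUAL", "WAKING_ONLY", "DREAM_ONLY", "TYPICAL_WAKING", "TYPICAL_DREAM")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-corpus draw.

    Defaults describe a mid-sized study: a 500-condition vocabulary whose
    frequencies decay as a Zipf law with exponent 1.2, a waking corpus of
    50 000 raw mentions, and 2 888 dream reports averaging ~1.3 conditions
    each — dream reports are small sets; survey collections of pandemic
    dreams average just over one extracted condition per report. Class
    fractions must sum to one.
    """

    n_conditions: int = 500
    zipf_exponent: float = 1.2
    n_mentions_waking: int = 50_000
    n_reports: int = 2_888
    report_size_mean: float = 1.3
    frac_shared: float = 0.4
    frac_waking_only: float = 0.15
    frac_dream_only: float = 0.15
    frac_waking_enriched: float = 0.15
    frac_dream_enriched: float = 0.15
    rank_shift: float = 150.0
    n_clusters: int = 8
    within_cluster_prob: float = 0.6
    seed: int = 42

    @property
    def fractions(self) -> tuple[float, float, float, float, float]:
        return (
            self.frac_shared,
            self.frac_waking_only,
            self.frac_dream_only,
            self.frac_waking_enriched,
            self.frac_dream_enriched,
        )

    def validate(self) -> None:
        for name in ("n_conditions", "n_mentions_waking", "n_reports", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.zipf_exponent <= 0 or self.rank_shift <= 0 or self.report_size_mean <= 0:
            raise ValueError("zipf_exponent, rank_shift and report_size_mean must be positive")
        fracs = self.fractions
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs)}")
        # within_cluster_prob must dominate the baseline mixing rate, else
        # clusters are not planted at all
        if not (1.0 / self.n_clusters <= self.within_cluster_prob <= 1.0):
            raise ValueError(
                "within_cluster_prob must lie in [1/n_clusters, 1]"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted class label and cluster id per condition."""

    class_of: dict[str, str]
    cluster_of: dict[str, int]


# -- vocabulary -------------------------------------------------------------

_ONSETS = "b br c ch cl d dr f fl g gr h j k l m n p pl pr qu r s sh sk sl sp st t th tr v w".split()
_NUCLEI = "a e i o u ai ea ia io ou".split()
_CODAS = [""] + "b ck d g l ll m n ng nk p r rm rn s sh ss st t th x".split()


def generate_vocabulary(n_conditions: int, seed: int) -> list[str]:
    """Generate `n_conditions` unique lowercase pseudo-word condition labels.

    Deterministic for a fixed seed. Labels are pronounceable syllable
    combinations; in the unlikely event the syllable space is exhausted a
    numeric suffix keeps labels unique.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(labels) < n_conditions:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _ONSETS[rng.integers(len(_ONSETS))]
            + _NUCLEI[rng.integers(len(_NUCLEI))]
            + (_CODAS[rng.integers(len(_CODAS))] if s == n_syll - 1 else "")
            for s in range(n_syll)
        )
        attempts += 1
        if word in seen:
            if attempts > 50 * n_conditions:
                word = f"{word}{len(labels)}"
            else:
                continue
        seen.add(word)
        labels.append(word)
    return labels


# -- class apportionment ----------------------------------------------------


def _apportion(fractions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n items across class fractions."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - int(counts.sum())
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


# -- corpus generation ------------------------------------------------------


def _zipf_weight(rank: np.ndarray | float, exponent: float) -> np.ndarray | float:
    return np.asarray(rank, dtype=float) ** (-exponent)


def generate_corpora(
    spec: SyntheticSpec,
) -> tuple[list[MentionRecord], list[ReportConditionSet], GroundTruth]:
    """Draw a waking mention corpus, dream reports and their ground truth.

    Base sampling weights follow a Zipf law over a random permutation of the
    vocabulary. Enriched conditions have their weight in the *other* corpus
    evaluated at Zipf rank ``base + rank_shift``, suppressing them there;
    exclusive conditions get zero weight in the other corpus. Reports are
    sets (a condition either occurs in a report or not), sized
    1 + Poisson(report_size_mean − 1), with cluster-biased filling.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = generate_vocabulary(spec.n_conditions, spec.seed)
    n = spec.n_conditions

    counts = _apportion(spec.fractions, n)
    labels = np.repeat(np.arange(5), counts)
    rng.shuffle(labels)
    class_of = {vocab[i]: CLASS_LABELS[labels[i]] for i in range(n)}

    # base Zipf ranks assigned in vocabulary order (vocab order is already a
    # random draw), displaced ranks for the suppressed corpus
    base_rank = np.arange(1, n + 1, dtype=float)
    base_w = _zipf_weight(base_rank, spec.zipf_exponent)
    shifted_w = _zipf_weight(base_rank + spec.rank_shift, spec.zipf_exponent)

    w_waking = base_w.copy()
    w_dreams = base_w.copy()
    w_waking[labels == 2] = 0.0  # DREAM_ONLY absent from waking
    w_dreams[labels == 1] = 0.0  # WAKING_ONLY absent from dreams
    w_waking[labels == 4] = shifted_w[labels == 4]  # TYPICAL_DREAM suppressed in waking
    w_dreams[labels == 3] = shifted_w[labels == 3]  # TYPICAL_WAKING suppressed in dreams

    # waking corpus: multinomial mention counts expanded to a shuffled stream
    if w_waking.sum() > 0:
        p_waking = w_waking / w_waking.sum()
        mention_counts = rng.multinomial(spec.n_mentions_waking, p_waking)
    else:  # every condition exclusive to dreams: waking corpus is empty
        mention_counts = np.zeros(n, dtype=int)
    stream = np.repeat(np.arange(n), mention_counts)
    rng.shuffle(stream)
    width = len(str(max(spec.n_mentions_waking - 1, 1)))
    waking = [
        MentionRecord(f"w{i:0{width}d}", "waking", vocab[int(c)])
        for i, c in enumerate(stream)
    ]

    # clusters: balanced partition of the whole vocabulary
    perm = rng.permutation(n)
    cluster_ids = np.empty(n, dtype=int)
    cluster_ids[perm] = np.arange(n) % spec.n_clusters
    cluster_of = {vocab[i]: int(cluster_ids[i]) for i in range(n)}

    dream_present = np.flatnonzero(w_dreams > 0)
    if dream_present.size == 0:  # every condition exclusive to waking
        return waking, [], GroundTruth(class_of=class_of, cluster_of=cluster_of)
    p_dreams = w_dreams / w_dreams.sum()
    cluster_members = {
        k: dream_present[cluster_ids[dream_present] == k]
        for k in range(spec.n_clusters)
    }
    cluster_probs = {}
    for k, members in cluster_members.items():
        w = p_dreams[members]
        cluster_probs[k] = w / w.sum() if w.sum() > 0 else None

    p_present = p_dreams[dream_present] / p_dreams[dream_present].sum()
    member_sets = {k: set(m.tolist()) for k, m in cluster_members.items()}
    reports: list[ReportConditionSet] = []
    rwidth = len(str(max(spec.n_reports - 1, 1)))
    for r in range(spec.n_reports):
        size = 1 + int(rng.poisson(max(spec.report_size_mean - 1.0, 0.0)))
        size = min(size, len(dream_present))
        seed_cond = int(dream_present[rng.choice(len(dream_present), p=p_present)])
        chosen = {seed_cond}
        k = int(cluster_ids[seed_cond])
        members, mprobs = cluster_members[k], cluster_probs[k]
        guard = 0
        while len(chosen) < size and guard < 50 * size:
            guard += 1
            if (
                mprobs is not None
                and rng.random() < spec.within_cluster_prob
                and len(chosen & member_sets[k]) < len(members)
            ):
                cand = int(members[rng.choice(len(members), p=mprobs)])
            else:
                cand = int(dream_present[rng.choice(len(dream_present), p=p_present)])
            chosen.add(cand)
        reports.append(
            ReportConditionSet(f"d{r:0{rwidth}d}", frozenset(vocab[c] for c in chosen))
        )

    return waking, reports, GroundTruth(class_of=class_of, cluster_of=cluster_of)


def generate_null_reports(
    n_reports: int, n_conditions: int, report_size: int, seed: int
) -> list[ReportConditionSet]:
    """Reports with no structure: uniform random fixed-size condition subsets.

    The null model for type-I-error checks of the edge filter: any edge that
    survives significance filtering on these reports is a false positive.
    """
    if n_conditions < 1 or report_size < 1:
        raise ValueError("n_conditions and report_size must be positive")
    if report_size > n_conditions:
        raise ValueError("report_size cannot exceed n_conditions")
    if n_reports < 0:
        raise ValueError("n_reports must be non-negative")
    rng = np.random.default_rng(seed)
    vocab = generate_vocabulary(n_conditions, seed)
    width = len(str(max(n_reports - 1, 1)))
    return [
        ReportConditionSet(
            f"n{r:0{width}d}",
            frozenset(vocab[int(c)] for c in rng.choice(n_conditions, size=report_size, replace=False)),
        )
        for r in range(n_reports)
    ]


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Write planted labels as TSV (condition, class, cluster)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["condition", "class", "cluster"])
        for cond in sorted(truth.class_of):
            writer.writerow([cond, truth.class_of[cond], truth.cluster_of[cond]])
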