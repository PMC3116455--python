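"""Synthetic PPI-like corpora with controlled synonym structure.

The generator stands in for external labelled/unlabelled corpora.  A
fixed number of trigger-word clusters is split into TRAIN and TEST
synonym subsets; positive sentences carry exactly one trigger (TRAIN
subset in the training block, TEST subset in the held-out block) plus at
least two protein mentions, negatives carry mentions but no trigger.
The companion unlabelled corpus makes TRAIN and TEST synonyms of the
same cluster co-occur at short distance with a configurable strength, so
co-occurrence models can recover the cluster structure.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .corpus import LabeledSentence


class GeneratorError(ValueError):
    pass


def _letters(i: int, width: int) -> str:
    out = []
    for _ in range(width):
        out.append(string.ascii_lowercase[i % 26])
        i //= 26
    return "".join(reversed(out))


@dataclass(frozen=True)
class GeneratorSpec:
    n_background: int = 200
    n_trigger_clusters: int = 10
    synonyms_per_cluster: int = 10
    n_labeled_sentences: int = 2000
    positive_rate: float = 0.3
    sentence_length: tuple[int, int] = (5, 12)
    n_unlabeled_sentences: int = 20000
    cooccurrence_strength: float = 0.9
    seed: int = 0
    holdout_fraction: float = 0.0
    leakage: float = 0.0
    abstract_block: int = 5
    event_rate: float = 0.5  # fraction of unlabelled sentences with a synonym pair

    def __post_init__(self) -> None:
        if min(
            self.n_background,
            self.n_trigger_clusters,
            self.synonyms_per_cluster,
            self.n_labeled_sentences,
            self.n_unlabeled_sentences,
            self.abstract_block,
        ) < 1:
            raise GeneratorError("all counts must be positive")
        if not 0.0 < self.positive_rate < 1.0:
            raise GeneratorError("positive_rate must be in (0, 1)")
        lo, hi = self.sentence_length
        if lo < 1 or hi < lo:
            raise GeneratorError(f"infeasible sentence lengths ({lo}, {hi})")
        if not 0.0 <= self.cooccurrence_strength <= 1.0:
            raise GeneratorError("co-occurrence strength must be in [0, 1]")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise GeneratorError("holdout_fraction must be in [0, 1)")
        if self.n_trigger_clusters > 26 or self.synonyms_per_cluster > 26:
            raise GeneratorError("at most 26 clusters of 26 synonyms supported")
        if self.holdout_fraction > 0 and self.synonyms_per_cluster < 2:
            raise GeneratorError(
                "held-out TEST synonyms require >= 2 synonyms per cluster"
            )

    @property
    def vocab_size(self) -> int:
        return self.n_background + self.n_trigger_clusters * self.synonyms_per_cluster

    def background_words(self) -> list[str]:
        return [f"bg{_letters(i, 3)}" for i in range(self.n_background)]

    def cluster_synonyms(self, c: int) -> list[str]:
        return [
            f"tg{string.ascii_lowercase[c]}{string.ascii_lowercase[s]}"
            for s in range(self.synonyms_per_cluster)
        ]

    def train_synonyms(self, c: int) -> list[str]:
        syn = self.cluster_synonyms(c)
        return syn[: max(1, (len(syn) + 1) // 2)]

    def test_synonyms(self, c: int) -> list[str]:
        syn = self.cluster_synonyms(c)
        return syn[max(1, (len(syn) + 1) // 2) :]

    def all_words(self) -> list[str]:
        words = self.background_words()
        for c in range(self.n_trigger_clusters):
            words.extend(self.cluster_synonyms(c))
        return words


_PROTEIN_POOL = [f"Prot{ch}" for ch in string.ascii_uppercase]


def _assemble_sentence(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    background: list[str],
    trigger: str | None,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    lo, hi = spec.sentence_length
    length = int(rng.integers(lo, hi + 1))
    words = [(str(w), False) for w in rng.choice(background, size=length)]
    if trigger is not None:
        words.insert(int(rng.integers(0, len(words) + 1)), (trigger, False))
    n_prot = 2 + int(rng.random() < 0.2)  # occasionally a third mention
    prot_names = rng.choice(_PROTEIN_POOL, size=n_prot, replace=False)
    positions = sorted(
        int(p) for p in rng.integers(0, len(words) + 1, size=n_prot)
    )
    for off, (pos, name) in enumerate(zip(positions, prot_names)):
        words.insert(pos + off, (str(name), True))
    spans: list[tuple[int, int]] = []
    cursor = 0
    for w, is_prot in words:
        if is_prot:
            spans.append((cursor, cursor + len(w)))
        cursor += len(w) + 1  # single-space join
    text = " ".join(w for w, _ in words)
    return text, tuple(spans)


def generate_labeled(spec: GeneratorSpec) -> list[LabeledSentence]:
    """Labelled corpus; the final ``holdout_fraction`` of sentences form a
    block whose positives use TEST-subset synonyms only."""
    rng = np.random.default_rng([spec.seed, 1])
    background = spec.background_words()
    n = spec.n_labeled_sentences
    n_hold = int(round(spec.holdout_fraction * n))
    sentences: list[LabeledSentence] = []
    for block_name, block_size, use_test in (
        ("tr", n - n_hold, False),
        ("te", n_hold, True),
    ):
        if block_size == 0:
            continue
        n_pos = int(round(spec.positive_rate * block_size))
        labels = np.zeros(block_size, dtype=int)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        for i in range(block_size):
            label = int(labels[i])
            trigger = None
            if label == 1 or (spec.leakage > 0 and rng.random() < spec.leakage):
                c = int(rng.integers(spec.n_trigger_clusters))
                pool = spec.test_synonyms(c) if use_test else spec.train_synonyms(c)
                trigger = str(rng.choice(pool))
            text, spans = _assemble_sentence(rng, spec, background, trigger)
            abstract_id = f"{block_name}ab{i // spec.abstract_block:05d}"
            sentences.append(
                LabeledSentence(
                    sentence_id=f"{block_name}{i:06d}",
                    abstract_id=abstract_id,
                    raw_text=text,
                    protein_spans=spans,
                    label=label,
                )
            )
    return sentences


def generate_unlabeled(spec: GeneratorSpec) -> list[list[str]]:
    """Unlabelled sentences where same-cluster TRAIN/TEST synonyms
    co-occur adjacently with probability ``cooccurrence_strength`` per
    synonym-pair event (otherwise the second synonym comes from a random
    cluster, i.e. background rate)."""
    rng = np.random.default_rng([spec.seed, 2])
    background = spec.background_words()
    lo, hi = spec.sentence_length
    out: list[list[str]] = []
    for _ in range(spec.n_unlabeled_sentences):
        length = int(rng.integers(lo, hi + 1))
        words = list(rng.choice(background, size=length))
        if rng.random() < spec.event_rate:
            c1 = int(rng.integers(spec.n_trigger_clusters))
            first = str(rng.choice(spec.cluster_synonyms(c1)))
            if rng.random() < spec.cooccurrence_strength:
                c2 = c1
            else:
                c2 = int(rng.integers(spec.n_trigger_clusters))
            second = str(rng.choice(spec.cluster_synonyms(c2)))
            pos = int(rng.integers(0, len(words)))
            words[pos:pos] = [first, second]
        if rng.random() < 0.3:
            pos = int(rng.integers(0, len(words)))
            words[pos:pos] = ["PTNGNE1", "PTNGNE2"]
        out.append(words)
    return out
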