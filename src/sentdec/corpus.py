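"""Synthetic multi-domain sentiment corpora with known ground truth.

The generator emulates the structure the decoupling framework assumes:
sentiment signal is carried by lexicon words with fixed polarity, domain
signal by domain-specific marker words, and the rest of each sentence is
neutral filler. Every planted quantity is recoverable, so tests can check
the model against the generating process rather than against opinions.

File formats: corpus as JSONL (one example per line), lexicon as two-column
TSV, vocabulary / markers / generator settings as JSON sidecars.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LabeledExample", "SentimentLexicon", "CorpusSpec", "Corpus",
    "generate_corpus", "make_domain_pair", "write_corpus", "read_corpus",
    "split_corpus", "corpus_to_csv",
]


class CorpusValidationError(ValueError):
    """A corpus specification or file violates a declared constraint."""


@dataclass(frozen=True)
class LabeledExample:
    """One token sequence with its sentiment label and domain label."""

    tokens: tuple[str, ...]
    sentiment_label: int
    domain_label: int
    example_id: str

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise CorpusValidationError("example must contain at least one token")


class SentimentLexicon:
    """Token -> polarity map with polarity in {-1, +1}.

    Lookup of an absent token is a distinguishable outcome (`None` from
    :meth:`polarity`, or a KeyError from indexing), never a default polarity.
    """

    def __init__(self, entries: Mapping[str, int]):
        for tok, pol in entries.items():
            if pol not in (-1, 1):
                raise CorpusValidationError(
                    f"lexicon polarity for {tok!r} must be -1 or +1, got {pol}")
        self._entries = dict(entries)

    def __contains__(self, token: str) -> bool:
        return token in self._entries

    def __getitem__(self, token: str) -> int:
        return self._entries[token]

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, SentimentLexicon) and self._entries == other._entries

    def polarity(self, token: str) -> int | None:
        """Polarity of `token`, or None when the token is not in the lexicon."""
        return self._entries.get(token)

    def tokens(self) -> list[str]:
        return sorted(self._entries)

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class CorpusSpec:
    """Generator settings; the single source of truth for a synthetic corpus.

    `domain_label_correlation` confounds domain with sentiment: with that
    probability an example's domain is set to ``label % n_domains`` instead
    of being drawn balanced. 0 keeps domain independent of the label.
    """

    n_examples: int = 2000
    vocab_size: int = 200
    n_domains: int = 2
    n_classes: int = 2
    lexicon_size_per_class: int = 12
    lexicon_tokens_per_example: int = 3
    domain_marker_tokens_per_example: int = 2
    marker_pool_size: int = 6
    label_flip_rate: float = 0.0
    sentence_length_range: tuple[int, int] = (8, 16)
    domain_label_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_examples < 0:
            raise CorpusValidationError("n_examples must be >= 0")
        if self.n_classes != 2:
            raise CorpusValidationError("only binary sentiment (n_classes=2) is supported")
        if self.n_domains < 1:
            raise CorpusValidationError("n_domains must be >= 1")
        if not (0.0 <= self.label_flip_rate <= 1.0):
            raise CorpusValidationError("label_flip_rate must lie in [0, 1]")
        if not (0.0 <= self.domain_label_correlation <= 1.0):
            raise CorpusValidationError("domain_label_correlation must lie in [0, 1]")
        reserved = (self.n_classes * self.lexicon_size_per_class
                    + self.n_domains * self.marker_pool_size)
        if self.vocab_size <= reserved:
            raise CorpusValidationError(
                f"vocab_size={self.vocab_size} must exceed lexicon+marker pool "
                f"size {reserved} (no room for neutral filler tokens)")
        lo, hi = self.sentence_length_range
        if lo > hi or lo < 1:
            raise CorpusValidationError("sentence_length_range must be (min, max) with 1 <= min <= max")
        planted = self.lexicon_tokens_per_example + self.domain_marker_tokens_per_example
        if lo < planted:
            raise CorpusValidationError(
                f"minimum sentence length {lo} cannot hold the {planted} planted tokens")
        if self.lexicon_tokens_per_example < 1:
            raise CorpusValidationError("lexicon_tokens_per_example must be >= 1")


@dataclass
class Corpus:
    examples: list[LabeledExample]
    vocabulary: list[str]
    lexicon: SentimentLexicon
    domain_markers: dict[int, frozenset[str]]
    spec: CorpusSpec = field(compare=False, default=None)

    def __post_init__(self):
        vocab = set(self.vocabulary)
        for ex in self.examples:
            unknown = set(ex.tokens) - vocab
            if unknown:
                raise CorpusValidationError(
                    f"example {ex.example_id}: tokens not in vocabulary: {sorted(unknown)[:5]}")
        marker_union: set[str] = set()
        for d, markers in self.domain_markers.items():
            if marker_union & markers:
                raise CorpusValidationError("domain marker sets must be pairwise disjoint")
            marker_union |= markers
        if any(m in self.lexicon for m in marker_union):
            raise CorpusValidationError("domain markers must be disjoint from the lexicon")

    def __len__(self) -> int:
        return len(self.examples)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Corpus)
                and self.examples == other.examples
                and self.vocabulary == other.vocabulary
                and self.lexicon == other.lexicon
                and self.domain_markers == other.domain_markers
                and self.spec == other.spec)

    def marker_domain(self, token: str) -> int | None:
        for d, markers in self.domain_markers.items():
            if token in markers:
                return d
        return None


def planted_majority_label(tokens: Sequence[str], lexicon: SentimentLexicon) -> int | None:
    """Label implied by the majority polarity of lexicon tokens (None if tied/absent)."""
    total = sum(lexicon.polarity(t) or 0 for t in tokens if t in lexicon)
    if total == 0:
        return None
    return 1 if total > 0 else 0


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a corpus fully determined by ``spec`` (including its seed).

    Before label flipping, each example's sentiment label equals the strict
    majority polarity of its planted lexicon tokens; each example carries
    exactly ``domain_marker_tokens_per_example`` markers of its own domain.
    Class and domain marginals are balanced to within one example (domain
    balance holds when ``domain_label_correlation`` is 0).
    """
    rng = np.random.default_rng(spec.seed)

    neg_lex = [f"neg{i}" for i in range(spec.lexicon_size_per_class)]
    pos_lex = [f"pos{i}" for i in range(spec.lexicon_size_per_class)]
    markers = {d: [f"dom{d}_m{j}" for j in range(spec.marker_pool_size)]
               for d in range(spec.n_domains)}
    n_filler = (spec.vocab_size - len(neg_lex) - len(pos_lex)
                - spec.n_domains * spec.marker_pool_size)
    fillers = [f"w{i}" for i in range(n_filler)]
    vocabulary = neg_lex + pos_lex + [m for d in sorted(markers) for m in markers[d]] + fillers
    lexicon = SentimentLexicon({**{t: -1 for t in neg_lex}, **{t: 1 for t in pos_lex}})
    class_lex = {0: neg_lex, 1: pos_lex}

    n = spec.n_examples
    planted = np.array([i % spec.n_classes for i in range(n)], dtype=int)
    rng.shuffle(planted)
    flips = rng.random(n) < spec.label_flip_rate
    observed = np.where(flips, 1 - planted, planted)
    base_domains = np.array([i % spec.n_domains for i in range(n)], dtype=int)
    rng.shuffle(base_domains)
    # confounding couples the domain with the *observed* label, so domain
    # markers carry label information even past the planted lexicon signal
    confound = rng.random(n) < spec.domain_label_correlation
    domains = np.where(confound, observed % spec.n_domains, base_domains)

    k_lex = spec.lexicon_tokens_per_example
    k_mark = spec.domain_marker_tokens_per_example
    lo, hi = spec.sentence_length_range
    examples: list[LabeledExample] = []
    for i in range(n):
        y, d = int(planted[i]), int(domains[i])
        length = int(rng.integers(lo, hi + 1))
        # strict-majority split of lexicon tokens between the label's class
        # lexicon and the opposite one
        n_major = int(rng.integers(k_lex // 2 + 1, k_lex + 1))
        lex_tokens = list(rng.choice(class_lex[y], size=n_major)) + \
            list(rng.choice(class_lex[1 - y], size=k_lex - n_major))
        mark_tokens = list(rng.choice(markers[d], size=k_mark))
        fill_tokens = list(rng.choice(fillers, size=length - k_lex - k_mark))
        tokens = np.array(lex_tokens + mark_tokens + fill_tokens, dtype=object)
        rng.shuffle(tokens)
        examples.append(LabeledExample(
            tokens=tuple(str(t) for t in tokens),
            sentiment_label=int(observed[i]), domain_label=d,
            example_id=f"ex{i:06d}"))

    return Corpus(examples=examples, vocabulary=vocabulary, lexicon=lexicon,
                  domain_markers={d: frozenset(v) for d, v in markers.items()},
                  spec=spec)


def make_domain_pair(example: LabeledExample, corpus: Corpus, target_domain: int,
                     rng: np.random.Generator | int | None = 0) -> LabeledExample:
    """Re-render ``example`` in ``target_domain`` by marker substitution.

    Every source-domain marker token is replaced by a seeded-random marker of
    the target domain; all other tokens and the sentiment label are unchanged.
    """
    if target_domain not in corpus.domain_markers:
        raise CorpusValidationError(f"unknown target domain {target_domain}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    source_domains = {corpus.marker_domain(t) for t in example.tokens} - {None}
    if len(source_domains) > 1:
        raise CorpusValidationError(
            f"example {example.example_id} mixes markers of domains {sorted(source_domains)}")
    target_pool = sorted(corpus.domain_markers[target_domain])
    new_tokens = tuple(
        str(rng.choice(target_pool)) if corpus.marker_domain(t) is not None else t
        for t in example.tokens)
    return dataclasses.replace(example, tokens=new_tokens, domain_label=target_domain)


# --------------------------------------------------------------------- I/O

def _sidecar(path: Path, suffix: str) -> Path:
    return path.parent / (path.stem + suffix)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write JSONL plus vocabulary/lexicon/marker/spec sidecar files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for ex in corpus.examples:
            fh.write(json.dumps({
                "tokens": list(ex.tokens),
                "sentiment_label": ex.sentiment_label,
                "domain_label": ex.domain_label,
                "example_id": ex.example_id,
            }) + "\n")
    _sidecar(path, ".vocab.json").write_text(
        json.dumps(corpus.vocabulary), encoding="utf-8")
    with _sidecar(path, ".lexicon.tsv").open("w", encoding="utf-8") as fh:
        for tok, pol in sorted(corpus.lexicon.items()):
            fh.write(f"{tok}\t{pol:+d}\n")
    _sidecar(path, ".markers.json").write_text(
        json.dumps({str(d): sorted(m) for d, m in corpus.domain_markers.items()}),
        encoding="utf-8")
    if corpus.spec is not None:
        _sidecar(path, ".spec.json").write_text(
            json.dumps(dataclasses.asdict(corpus.spec)), encoding="utf-8")


def read_lexicon(path: str | Path) -> SentimentLexicon:
    entries: dict[str, int] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
            try:
                entries[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise CorpusValidationError(
                    f"{path}:{lineno}: polarity {parts[1]!r} is not an integer") from exc
    return SentimentLexicon(entries)


def read_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    vocabulary = json.loads(_sidecar(path, ".vocab.json").read_text(encoding="utf-8"))
    lexicon = read_lexicon(_sidecar(path, ".lexicon.tsv"))
    markers_raw = json.loads(_sidecar(path, ".markers.json").read_text(encoding="utf-8"))
    domain_markers = {int(d): frozenset(m) for d, m in markers_raw.items()}
    spec = None
    spec_path = _sidecar(path, ".spec.json")
    if spec_path.exists():
        raw = json.loads(spec_path.read_text(encoding="utf-8"))
        raw["sentence_length_range"] = tuple(raw["sentence_length_range"])
        spec = CorpusSpec(**raw)

    vocab_set = set(vocabulary)
    examples: list[LabeledExample] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                ex = LabeledExample(
                    tokens=tuple(rec["tokens"]),
                    sentiment_label=int(rec["sentiment_label"]),
                    domain_label=int(rec["domain_label"]),
                    example_id=str(rec["example_id"]))
            except (KeyError, ValueError, TypeError) as exc:
                raise CorpusValidationError(f"{path}:{lineno}: malformed record: {exc}") from exc
            unknown = set(ex.tokens) - vocab_set
            if unknown:
                raise CorpusValidationError(
                    f"{path}:{lineno}: tokens not in vocabulary sidecar: {sorted(unknown)[:5]}")
            examples.append(ex)
    return Corpus(examples=examples, vocabulary=vocabulary, lexicon=lexicon,
                  domain_markers=domain_markers, spec=spec)


def corpus_to_csv(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["example_id", "text", "sentiment_label", "domain_label"])
        for ex in corpus.examples:
            writer.writerow([ex.example_id, " ".join(ex.tokens),
                             ex.sentiment_label, ex.domain_label])


# ------------------------------------------------------------------- splits

def split_corpus(corpus: Corpus, fractions: tuple[float, float, float],
                 seed: int = 0) -> tuple[Corpus, Corpus, Corpus]:
    """Stratified train/val/test split by (sentiment_label, domain_label).

    Per-stratum allocation uses floors plus a global largest-remainder
    correction so overall split sizes match ``n * fractions`` as closely as
    an integer partition allows.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise CorpusValidationError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise CorpusValidationError("fractions must sum to 1")

    strata: dict[tuple[int, int], list[LabeledExample]] = {}
    for ex in corpus.examples:
        strata.setdefault((ex.sentiment_label, ex.domain_label), []).append(ex)
    for key, members in strata.items():
        if len(members) < 3:
            raise CorpusValidationError(
                f"stratum {key} has only {len(members)} examples; "
                "generate a larger corpus to split")

    rng = np.random.default_rng(seed)
    n = len(corpus.examples)
    global_target = [n * f for f in fractions]
    assigned = [0, 0, 0]
    buckets: tuple[list[LabeledExample], ...] = ([], [], [])
    for key in sorted(strata):
        members = list(strata[key])
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        m = len(members)
        exact = [m * f for f in fractions]
        counts = [int(np.floor(e)) for e in exact]
        leftover = m - sum(counts)
        rem = [exact[j] - np.floor(exact[j]) for j in range(3)]
        for _ in range(leftover):
            # largest remainder wins; global deficit breaks ties so equal
            # remainders alternate across strata instead of piling up
            need = [global_target[j] - (assigned[j] + counts[j]) for j in range(3)]
            j = max(range(3), key=lambda j: (rem[j], need[j], -j))
            counts[j] += 1
            rem[j] -= 1.0
        pos = 0
        for j in range(3):
            buckets[j].extend(members[pos:pos + counts[j]])
            assigned[j] += counts[j]
            pos += counts[j]

    def view(members: list[LabeledExample]) -> Corpus:
        members = sorted(members, key=lambda e: e.example_id)
        return Corpus(examples=members, vocabulary=corpus.vocabulary,
                      lexicon=corpus.lexicon, domain_markers=corpus.domain_markers,
                      spec=corpus.spec)

    return view(buckets[0]), view(buckets[1]), view(buckets[2])
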