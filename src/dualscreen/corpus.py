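"""Corpus handling: labeled records, text cleaning, tokenization, severity
binning and the stratified train/validation/test split.

Records carry a free-text response together with the two ordinal screening
scores: PHQ-9 (depression, 0-27 points) and GAD-7 (anxiety, 0-21 points).
Both scales are binned into three severity levels (mild 0-4, moderate 5-9,
severe >= 10) and screened positive at the clinical threshold of 10 points.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

log = logging.getLogger(__name__)

PHQ9_MAX = 27
GAD7_MAX = 21
SCREEN_THRESHOLD = 10
SEVERITY_LEVELS = ("mild", "moderate", "severe")

#: punctuation retained because it carries emotional signal (exclamation,
#: question, ellipsis, tilde) plus neutral clause punctuation kept in a
#: normalized full-width form. Configurable via ``clean_text(keep=...)``.
EMOTION_PUNCT = "！？…~"
NEUTRAL_PUNCT = "，。、；："


class SchemaError(ValueError):
    """A required column/key is missing from the input file."""


class ValidationError(ValueError):
    """A record violates a score-range or non-emptiness invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabeledText:
    record_id: str
    text: str
    phq9: int
    gad7: int
    subject_id: str | None = None
    cohort: str | None = None
    synthetic: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phq9 = int(self.phq9)
        self.gad7 = int(self.gad7)
        if not 0 <= self.phq9 <= PHQ9_MAX:
            raise ValidationError(
                f"record {self.record_id!r}: phq9={self.phq9} outside [0, {PHQ9_MAX}]"
            )
        if not 0 <= self.gad7 <= GAD7_MAX:
            raise ValidationError(
                f"record {self.record_id!r}: gad7={self.gad7} outside [0, {GAD7_MAX}]"
            )

    @property
    def phq9_severity(self) -> str:
        return severity_bin(self.phq9)

    @property
    def gad7_severity(self) -> str:
        return severity_bin(self.gad7)

    @property
    def stratum(self) -> tuple[str, str]:
        """Joint PHQ x GAD severity stratum used for stratification."""
        return (self.phq9_severity, self.gad7_severity)


@dataclass
class TokenizedSample:
    token_ids: np.ndarray
    attention_mask: np.ndarray
    length: int


@dataclass
class SplitDataset:
    train: list[LabeledText]
    validation: list[LabeledText]
    test: list[LabeledText]
    seed: int

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


# ---------------------------------------------------------------------------
# severity + screening
# ---------------------------------------------------------------------------

def severity_bin(score: int) -> str:
    """Map a scale score to its severity level: 0-4 mild, 5-9 moderate,
    >= 10 severe."""
    score = int(score)
    if score < 0:
        raise ValidationError(f"negative score {score}")
    if score <= 4:
        return "mild"
    if score <= 9:
        return "moderate"
    return "severe"


def screen_positive(score: int, scale: str) -> bool:
    """Binary clinical screen: positive iff score >= 10 (both scales)."""
    limit = {"phq9": PHQ9_MAX, "gad7": GAD7_MAX}.get(scale)
    if limit is None:
        raise ValueError(f"unknown scale {scale!r}")
    score = int(score)
    if not 0 <= score <= limit:
        raise ValidationError(f"{scale} score {score} outside [0, {limit}]")
    return score >= SCREEN_THRESHOLD


# ---------------------------------------------------------------------------
# text cleaning
# ---------------------------------------------------------------------------

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MARKUP_RE = re.compile(r"<[^<>]*>")
_ELLIPSIS_RE = re.compile(r"(?:\.{2,}|。{2,}|…+)")
# half-width -> full-width normalisation for retained punctuation
_PUNCT_NORM = str.maketrans({
    "!": "！", "?": "？", ",": "，", ".": "。", ";": "；", ":": "：", "～": "~",
})


def clean_text(raw: str, keep: str = EMOTION_PUNCT + NEUTRAL_PUNCT) -> str:
    """Clean a raw response: strip URLs/markup/control characters, drop
    special symbols, normalise punctuation to a single (full-width) form
    while preserving emotion-expressive punctuation, collapse whitespace.

    May return an empty string (e.g. all-symbol input); the caller decides
    whether to drop or keep such records.
    """
    text = _URL_RE.sub(" ", raw)
    text = _MARKUP_RE.sub(" ", text)
    text = _ELLIPSIS_RE.sub("…", text)
    text = text.translate(_PUNCT_NORM)
    out = []
    for ch in text:
        if ch.isspace():
            out.append(" ")
            continue
        cat = unicodedata.category(ch)
        if cat[0] in ("L", "N") or ch in keep:
            out.append(ch)
        # anything else (controls, symbols, unlisted punctuation) is dropped
    return re.sub(r"\s+", " ", "".join(out)).strip()


# ---------------------------------------------------------------------------
# tokenizers
# ---------------------------------------------------------------------------

class Tokenizer(Protocol):
    pad_id: int
    unk_id: int

    def encode(self, text: str) -> list[int]: ...

    @property
    def vocab_size(self) -> int: ...


class WhitespaceTokenizer:
    """Deterministic word-level tokenizer with a corpus-fitted vocabulary.

    Ids 0/1/2 are reserved for PAD/UNK/CLS; every encoded sequence starts
    with CLS. Pre-segmented (e.g. jieba) text can be fed directly since
    segmentation only needs to insert spaces.
    """

    pad_id, unk_id, cls_id = 0, 1, 2

    def __init__(self, vocab: dict[str, int] | None = None):
        self.vocab = vocab or {}

    @classmethod
    def fit(cls, texts: Iterable[str], min_count: int = 1) -> "WhitespaceTokenizer":
        counts: dict[str, int] = {}
        for t in texts:
            for w in t.split():
                counts[w] = counts.get(w, 0) + 1
        vocab = {}
        for w in sorted(counts):
            if counts[w] >= min_count:
                vocab[w] = len(vocab) + 3
        return cls(vocab)

    def encode(self, text: str) -> list[int]:
        return [self.cls_id] + [self.vocab.get(w, self.unk_id) for w in text.split()]

    @property
    def vocab_size(self) -> int:
        return len(self.vocab) + 3


class CharTokenizer:
    """Character-level fallback (no segmentation required)."""

    pad_id, unk_id, cls_id = 0, 1, 2

    def __init__(self, vocab: dict[str, int] | None = None):
        self.vocab = vocab or {}

    @classmethod
    def fit(cls, texts: Iterable[str]) -> "CharTokenizer":
        chars = sorted({c for t in texts for c in t if not c.isspace()})
        return cls({c: i + 3 for i, c in enumerate(chars)})

    def encode(self, text: str) -> list[int]:
        return [self.cls_id] + [
            self.vocab.get(c, self.unk_id) for c in text if not c.isspace()
        ]

    @property
    def vocab_size(self) -> int:
        return len(self.vocab) + 3


def tokenize(text: str, tokenizer: Tokenizer, max_len: int = 96) -> TokenizedSample:
    """Encode ``text`` and truncate to ``max_len`` tokens; the attention
    mask marks real tokens with 1."""
    if not text.strip():
        raise ValidationError("cannot tokenize empty text")
    ids = tokenizer.encode(text)[:max_len]
    return TokenizedSample(
        token_ids=np.asarray(ids, dtype=np.int64),
        attention_mask=np.ones(len(ids), dtype=np.int64),
        length=len(ids),
    )


def pad_batch(samples: Sequence[TokenizedSample], pad_id: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length samples into (ids, mask) arrays of shape (B, L)."""
    L = max(s.length for s in samples)
    ids = np.full((len(samples), L), pad_id, dtype=np.int64)
    mask = np.zeros((len(samples), L), dtype=np.int64)
    for i, s in enumerate(samples):
        ids[i, : s.length] = s.token_ids
        mask[i, : s.length] = s.attention_mask
    return ids, mask


# ---------------------------------------------------------------------------
# corpus reading / writing
# ---------------------------------------------------------------------------

_REQUIRED = ("text", "phq9", "gad7")


def _record_from_mapping(obj: dict, default_id: str) -> LabeledText:
    missing = [k for k in _REQUIRED if k not in obj or obj[k] in ("", None)]
    if missing:
        raise SchemaError(f"record {default_id}: missing required field(s) {missing}")
    return LabeledText(
        record_id=str(obj.get("record_id", default_id)),
        text=str(obj["text"]),
        phq9=int(obj["phq9"]),
        gad7=int(obj["gad7"]),
        subject_id=obj.get("subject_id") or None,
        cohort=obj.get("cohort") or None,
        synthetic=bool(obj.get("synthetic", False)),
    )


def read_corpus(path: str | Path, fmt: str | None = None, clean: bool = False) -> list[LabeledText]:
    """Read a labeled corpus from JSONL (one object per line) or CSV.

    ``fmt`` is inferred from the suffix when omitted. With ``clean=True``
    each text passes through :func:`clean_text`; records that clean to the
    empty string are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list[LabeledText] = []
    if fmt == "jsonl":
        with io.open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                records.append(_record_from_mapping(json.loads(line), f"row{i}"))
    elif fmt == "csv":
        with io.open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                reader.fieldnames = []
            missing = [k for k in _REQUIRED if k not in reader.fieldnames]
            if missing:
                raise SchemaError(f"CSV header missing column(s) {missing}")
            for i, row in enumerate(reader):
                records.append(_record_from_mapping(row, f"row{i}"))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    if not records:
        log.warning("corpus file %s is empty", path)
    if clean:
        kept = []
        for r in records:
            cleaned = clean_text(r.text)
            if cleaned:
                r.text = cleaned
                kept.append(r)
            else:
                log.warning("record %s empty after cleaning; dropped", r.record_id)
        records = kept
    return records


def write_corpus(records: Iterable[LabeledText], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with io.open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = asdict(r)
            if not obj["provenance"]:
                obj.pop("provenance")
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def _part_targets(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Global part sizes. Train takes round(f_train * N); of the remainder
    the validation part receives the larger half when odd — the rounding
    convention that yields 1,020/128/127 for N = 1,275 at 8:1:1."""
    total = float(sum(ratios))
    n_train = int(round(ratios[0] / total * n))
    rem = n - n_train
    f_val = ratios[1] / (ratios[1] + ratios[2])
    n_val = int(math.ceil(rem * f_val))
    return n_train, n_val, rem - n_val


def stratified_split(
    corpus: Sequence[LabeledText],
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
    by_subject: bool = False,
) -> SplitDataset:
    """Split a corpus into train/validation/test, stratified on the joint
    PHQ x GAD severity bin (3x3 grid).

    Allocation is per-stratum proportional with floors, then leftovers are
    assigned greedily by fractional remainder under the global part targets,
    so each part's per-stratum count differs from proportionality by at most
    one sample. Strata with fewer than 3 units go entirely to train. With
    ``by_subject`` the unit of allocation is the subject (all of a subject's
    records travel together); default is record-level.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)

    # allocation units: single records, or per-subject record groups
    if by_subject:
        groups: dict[str, list[LabeledText]] = {}
        for r in corpus:
            groups.setdefault(r.subject_id or r.record_id, []).append(r)
        units = [tuple(v) for _, v in sorted(groups.items())]

        def unit_stratum(u):
            return (
                severity_bin(int(round(np.mean([r.phq9 for r in u])))),
                severity_bin(int(round(np.mean([r.gad7 for r in u])))),
            )
    else:
        units = [(r,) for r in corpus]

        def unit_stratum(u):
            return u[0].stratum

    strata: dict[tuple[str, str], list] = {}
    for u in units:
        strata.setdefault(unit_stratum(u), []).append(u)

    small, regular = {}, {}
    for key in sorted(strata):
        (small if len(strata[key]) < 3 else regular)[key] = strata[key]
    for key, members in small.items():
        log.warning("stratum %s has %d unit(s) < 3; allocated to train", key, len(members))

    n_small = sum(len(v) for v in small.values())
    targets = list(_part_targets(len(units), tuple(ratios)))
    targets[0] -= n_small  # small strata pre-assigned to train
    if targets[0] < 0:
        # degenerate: shift the overflow out of validation, then test
        for p in (1, 2):
            take = min(-targets[0], targets[p])
            targets[p] -= take
            targets[0] += take

    fracs = np.asarray(ratios, dtype=float) / sum(ratios)
    floors: dict[tuple[str, str], list[int]] = {}
    remainders: list[tuple[float, tuple[str, str], int]] = []
    for key, members in regular.items():
        n_s = len(members)
        fl = [int(math.floor(f * n_s)) for f in fracs]
        floors[key] = fl
        for part in range(3):
            remainders.append((fracs[part] * n_s - fl[part], key, part))

    deficits = [t - sum(floors[k][p] for k in floors) for p, t in enumerate(targets)]
    leftover = {k: len(regular[k]) - sum(floors[k]) for k in regular}
    for _, key, part in sorted(remainders, key=lambda x: (-x[0], x[1], x[2])):
        if leftover.get(key, 0) > 0 and deficits[part] > 0:
            floors[key][part] += 1
            leftover[key] -= 1
            deficits[part] -= 1
    # mop up any residue (possible under pathological rounding)
    for key in sorted(leftover):
        while leftover[key] > 0:
            part = int(np.argmax(deficits))
            floors[key][part] += 1
            leftover[key] -= 1
            deficits[part] -= 1

    parts: list[list[LabeledText]] = [[], [], []]
    for key, members in small.items():
        order = rng.permutation(len(members))
        for i in order:
            parts[0].extend(members[i])
    for key in sorted(regular):
        members = regular[key]
        order = rng.permutation(len(members))
        counts = floors[key]
        pos = 0
        for part in range(3):
            for i in order[pos: pos + counts[part]]:
                parts[part].extend(members[i])
            pos += counts[part]
    return SplitDataset(train=parts[0], validation=parts[1], test=parts[2], seed=seed)


def split_report(split: SplitDataset):
    """Per-stratum count table for the three parts (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for phq in SEVERITY_LEVELS:
        for gad in SEVERITY_LEVELS:
            key = (phq, gad)
            rows.append({
                "phq9_severity": phq,
                "gad7_severity": gad,
                "train": sum(1 for r in split.train if r.stratum == key),
                "validation": sum(1 for r in split.validation if r.stratum == key),
                "test": sum(1 for r in split.test if r.stratum == key),
            })
    df = pd.DataFrame(rows)
    df["total"] = df[["train", "validation", "test"]].sum(axis=1)
    return df
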