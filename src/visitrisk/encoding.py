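"""Vocabulary pipeline: lab filtering, code mapping, and integer encoding.

The feature space of the sequence models is built in four steps, mirroring
common EMR practice:

1. lab events are restricted to abnormal results (RESULT_FLAG in
   ABNORMAL/HIGH/LOW, case-insensitive) and to the *k* most frequently
   tested lab codes (default 709);
2. ICD-9 diagnosis codes are translated to ICD-10 with a CMS General
   Equivalence Mappings (GEM) table, and every ICD-10 code is truncated to
   its 3-character category;
3. medication names are normalized (dose and form tokens stripped) and
   looked up in a name -> identifier dictionary;
4. the surviving tokens, namespaced by domain ("DX:", "MED:", "LAB:"), are
   ranked by training-corpus frequency and assigned integer indices
   1..max_size-1 (0 is reserved for padding); out-of-vocabulary tokens are
   dropped at encode time with a running count.

A lab code contributes one token regardless of which abnormal flag it
carried: the flags gate inclusion but do not split tokens. The post-hoc
flag-composition question ("how often was this lab LOW rather than HIGH?")
is answered by :func:`flag_proportions` instead.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import CohortSample, Visit
from .synthetic import EventRecord

logger = logging.getLogger(__name__)

ABNORMAL_FLAGS = frozenset({"ABNORMAL", "HIGH", "LOW"})


# ---------------------------------------------------------------------------
# lab filtering


def filter_abnormal_labs(events: list[EventRecord]) -> list[EventRecord]:
    """Keep LAB events whose flag is ABNORMAL/HIGH/LOW; non-lab untouched.

    Flag comparison trims whitespace and ignores case. LAB events with a
    missing flag are dropped (counted in the log).
    """
    kept, dropped_missing = [], 0
    for ev in events:
        if ev.domain != "LAB":
            kept.append(ev)
            continue
        if ev.result_flag is None or not ev.result_flag.strip():
            dropped_missing += 1
            continue
        if ev.result_flag.strip().upper() in ABNORMAL_FLAGS:
            kept.append(ev)
    if dropped_missing:
        logger.info("filter_abnormal_labs: dropped %d LAB events without a flag", dropped_missing)
    return kept


def top_k_labs(events: list[EventRecord], k: int) -> tuple[list[EventRecord], list[str]]:
    """Keep events of the k most frequent lab codes (corpus-wide count).

    Ties at rank k break lexicographically by code, so the retained set is
    deterministic. Non-lab events pass through.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(ev.code for ev in events if ev.domain == "LAB")
    ranked = sorted(counts.items(), key=lambda it: (-it[1], it[0]))
    retained = [code for code, _ in ranked[:k]]
    retained_set = set(retained)
    kept = [ev for ev in events if ev.domain != "LAB" or ev.code in retained_set]
    return kept, retained


def flag_proportions(events: list[EventRecord]) -> pd.DataFrame:
    """Per-lab-code RESULT_FLAG composition.

    Returns a tidy frame with one row per (code, flag): columns ``code``,
    ``flag``, ``count``, ``total`` and ``proportion`` = count/total at full
    precision (round only for display).
    """
    rows = [(ev.code, (ev.result_flag or "").strip().upper())
            for ev in events if ev.domain == "LAB"]
    if not rows:
        return pd.DataFrame(columns=["code", "flag", "count", "total", "proportion"])
    df = pd.DataFrame(rows, columns=["code", "flag"])
    counts = df.groupby(["code", "flag"], sort=True).size().rename("count").reset_index()
    totals = counts.groupby("code")["count"].transform("sum")
    counts["total"] = totals
    counts["proportion"] = counts["count"] / counts["total"]
    return counts


# ---------------------------------------------------------------------------
# diagnosis mapping


class GemParseError(ValueError):
    pass


class GemMap:
    """CMS General Equivalence Mappings, source -> list of targets.

    The file format is whitespace-delimited triplets per line:
    ``source target flags`` with a 5-character flag string
    (approximate, no-map, combination, scenario, choice list).
    A set no-map flag (second character ``1``) yields no target; combination
    mappings contribute every listed target.
    """

    def __init__(self, mapping: dict[str, list[str]]):
        self.mapping = mapping
        self.miss_count = 0

    @classmethod
    def from_file(cls, path) -> "GemMap":
        mapping: dict[str, list[str]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3 or len(parts[2]) != 5 or not parts[2].isdigit():
                raise GemParseError(f"malformed GEM row at line {lineno}: {line!r}")
            source, target, flags = parts
            no_map = flags[1] == "1"
            targets = mapping.setdefault(source, [])
            if not no_map and target not in targets:
                targets.append(target)
        return cls(mapping)

    def map_icd9(self, code: str) -> list[str]:
        """All GEM targets for an ICD-9 code; empty when unmapped (counted)."""
        targets = self.mapping.get(code, [])
        if not targets:
            self.miss_count += 1
        return list(targets)


def truncate_icd10(code: str) -> str:
    """3-character ICD-10 category (the dot falls after position 3)."""
    code = code.strip()
    if len(code) < 3:
        raise ValueError(f"ICD-10 code too short to truncate: {code!r}")
    return code[:3].upper()


# ---------------------------------------------------------------------------
# medication mapping

_DOSE_UNIT_TOKENS = frozenset({
    "mg", "mcg", "gm", "g", "ml", "unit", "units",
    "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap", "caps",
    "solution", "suspension", "syringe", "kit", "drops", "drop",
})
_NUMERIC_RE = re.compile(r"^[\d.,/]+$")


def normalize_medication_name(name: str) -> str:
    """Lowercase; strip dose, unit and form tokens; collapse whitespace.

    Idempotent: normalizing a normalized name is a no-op.
    """
    tokens = []
    for tok in name.lower().split():
        if "%" in tok or _NUMERIC_RE.match(tok) or tok in _DOSE_UNIT_TOKENS:
            continue
        tokens.append(tok)
    return " ".join(tokens)


def load_med_dict(path) -> dict[str, str]:
    """Two-column TSV: normalized medication name -> identifier."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "identifier"], dtype=str)
    return {normalize_medication_name(n): i for n, i in zip(df["name"], df["identifier"])}


def map_medication(name: str, med_dict: dict[str, str]) -> str | None:
    """Exact lookup of the normalized name; None (and a log line) on a miss."""
    key = normalize_medication_name(name)
    ident = med_dict.get(key)
    if ident is None:
        logger.debug("map_medication: no identifier for %r (normalized %r)", name, key)
    return ident


# ---------------------------------------------------------------------------
# vocabulary


class Vocabulary:
    """Frequency-ranked token -> index map; index 0 reserved for padding."""

    def __init__(self, index: dict[str, int], counts: dict[str, int]):
        self.index = index
        self.counts = counts
        self.oov_count = 0

    @classmethod
    def build(cls, token_counts: Counter, max_size: int = 30_000) -> "Vocabulary":
        """Index the ``max_size - 1`` most frequent tokens from 1 upward.

        Ties break lexicographically so the mapping is deterministic.
        """
        ranked = sorted(token_counts.items(), key=lambda it: (-it[1], it[0]))
        kept = ranked[: max_size - 1]
        index = {tok: i + 1 for i, (tok, _) in enumerate(kept)}
        return cls(index, dict(kept))

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def encode_tokens(self, tokens) -> list[int]:
        """Sorted unique indices of the in-vocabulary tokens; OOV counted."""
        out = set()
        for tok in tokens:
            idx = self.index.get(tok)
            if idx is None:
                self.oov_count += 1
            else:
                out.add(idx)
        return sorted(out)

    def decode(self, indices) -> list[str]:
        rev = {i: t for t, i in self.index.items()}
        return [rev[i] for i in indices]

    def save(self, path) -> None:
        df = pd.DataFrame(
            [(t, i, self.counts.get(t, 0)) for t, i in sorted(self.index.items(), key=lambda it: it[1])],
            columns=["token", "index", "count"],
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"token": str, "index": int, "count": int})
        return cls(dict(zip(df["token"], df["index"])), dict(zip(df["token"], df["count"])))


# ---------------------------------------------------------------------------
# the encoder


@dataclass
class EncodingConfig:
    k_labs: int = 709
    max_vocab: int = 30_000
    gem_path: str | None = None
    med_dict_path: str | None = None
    #: domains included in the feature space (ablation hook)
    domains: tuple[str, ...] = ("DX", "MED", "LAB")


@dataclass
class EncodedSample:
    patient_id: str
    index_date: object
    label: int
    #: list of (days_before_index, sorted unique token indices), oldest first
    visits: list[tuple[int, list[int]]] = field(default_factory=list)


class FeatureEncoder:
    """Token pipeline + vocabulary, fitted on the training partition only."""

    def __init__(self, config: EncodingConfig | None = None):
        self.config = config or EncodingConfig()
        self.gem = GemMap.from_file(self.config.gem_path) if self.config.gem_path else None
        self.med_dict = load_med_dict(self.config.med_dict_path) if self.config.med_dict_path else None
        self.retained_labs: set[str] | None = None
        self.vocab: Vocabulary | None = None

    # -- token derivation ---------------------------------------------------

    def event_tokens(self, domain: str, code: str, flag: str | None) -> list[str]:
        """Namespaced feature tokens for one raw event (possibly several for
        GEM combination mappings, possibly none for drops)."""
        if domain not in self.config.domains:
            return []
        if domain == "LAB":
            if flag is None or flag.strip().upper() not in ABNORMAL_FLAGS:
                return []
            if self.retained_labs is not None and code not in self.retained_labs:
                return []
            return [f"LAB:{code}"]
        if domain == "MED":
            if self.med_dict is not None:
                ident = map_medication(code, self.med_dict)
                if ident is None:
                    return []
                return [f"MED:{ident}"]
            return [f"MED:{code}"]
        # DX: ICD-9 sources run through the GEM first; everything is
        # truncated to the 3-character ICD-10 category.
        codes = [code]
        if self.gem is not None and code in self.gem.mapping:
            codes = self.gem.map_icd9(code)
        out = []
        for c in codes:
            tok = f"DX:{truncate_icd10(c)}"
            if tok not in out:
                out.append(tok)
        return out

    def visit_tokens(self, visit: Visit) -> list[str]:
        toks: list[str] = []
        for domain, code, flag in visit.events:
            for t in self.event_tokens(domain, code, flag):
                if t not in toks:
                    toks.append(t)
        return toks

    # -- fitting ------------------------------------------------------------

    def fit(self, train_samples: list[CohortSample]) -> "FeatureEncoder":
        """Fit lab retention and the vocabulary on training samples only."""
        lab_counts: Counter = Counter()
        for s in train_samples:
            for v in s.history:
                for domain, code, flag in v.events:
                    if domain == "LAB" and flag and flag.strip().upper() in ABNORMAL_FLAGS:
                        lab_counts[code] += 1
        ranked = sorted(lab_counts.items(), key=lambda it: (-it[1], it[0]))
        self.retained_labs = {code for code, _ in ranked[: self.config.k_labs]}

        token_counts: Counter = Counter()
        for s in train_samples:
            for v in s.history:
                token_counts.update(self.visit_tokens(v))
        self.vocab = Vocabulary.build(token_counts, self.config.max_vocab)
        return self

    # -- encoding -----------------------------------------------------------

    def encode_sample(self, sample: CohortSample) -> EncodedSample:
        """Integer-encode one sample; empty (all-OOV) visits are dropped.

        Visits are emitted oldest -> newest.
        """
        if self.vocab is None:
            raise RuntimeError("encoder not fitted; call fit() on the training partition first")
        visits = []
        for v in sorted(sample.history, key=lambda v: -v.days_before_index):
            idx = self.vocab.encode_tokens(self.visit_tokens(v))
            if idx:
                visits.append((v.days_before_index, idx))
        return EncodedSample(sample.patient_id, sample.index_date, sample.label, visits)

    def encode(self, samples: list[CohortSample]) -> list[EncodedSample]:
        return [self.encode_sample(s) for s in samples]
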