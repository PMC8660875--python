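"""Reading, normalising and tabulating category verbal-fluency transcripts.

A transcript is one row per produced response (participant id, group label,
production rank, raw response string).  Responses are canonicalised with a
table-driven variant map (orthographic/root merging), optionally restricted
to a category lexicon, deduplicated, and tabulated into binary
participants x exemplars response matrices — the input format every
downstream network-estimation step consumes.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluencyRecord",
    "NormalizationRules",
    "ResponseMatrix",
    "canonical_form",
    "normalize_responses",
    "build_response_matrix",
    "fluency_descriptives",
    "read_transcripts",
    "write_transcripts",
    "read_variant_map",
    "read_lexicon",
]


def canonical_form(raw: str) -> str:
    """Whitespace-trimmed, case-folded, accent-stripped form of a response.

    Accent stripping (NFKD decomposition, combining marks removed) merges
    orthographic variants such as "léopard"/"leopard", which matters for
    French-language fluency data.
    """
    s = " ".join(raw.split()).casefold()
    s = unicodedata.normalize("NFKD", s)
    return "".join(ch for ch in s if not unicodedata.combining(ch))


@dataclass(frozen=True)
class FluencyRecord:
    """One participant's ordered fluency responses with a group label."""

    participant_id: str
    group: str
    responses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))


@dataclass
class NormalizationRules:
    """Table-driven response normalisation: variant map plus optional lexicon.

    ``variant_map`` sends raw canonical-form keys to canonical exemplars
    (e.g. ``{"cats": "cat"}``); canonical exemplars must be fixed points of
    the map.  ``lexicon``, if given, is the set of admissible canonical
    exemplars; responses outside it are dropped (off-category items).
    """

    variant_map: Mapping[str, str] = field(default_factory=dict)
    lexicon: frozenset[str] | None = None

    def __post_init__(self) -> None:
        vmap = {
            canonical_form(k): canonical_form(v) for k, v in self.variant_map.items()
        }
        for key, value in vmap.items():
            if vmap.get(value, value) != value:
                raise ValueError(
                    f"canonical form {value!r} (from variant {key!r}) is not a "
                    "fixed point of the variant map"
                )
        self.variant_map = vmap
        if self.lexicon is not None:
            lex = frozenset(canonical_form(w) for w in self.lexicon)
            not_canonical = {w for w in lex if vmap.get(w, w) != w}
            if not_canonical:
                raise ValueError(
                    f"lexicon entries are not canonical forms: {sorted(not_canonical)}"
                )
            self.lexicon = lex


def normalize_responses(
    record: FluencyRecord, rules: NormalizationRules | None = None
) -> FluencyRecord:
    """Canonicalise, map variants, filter by lexicon, and deduplicate.

    First-occurrence order is preserved.  Responses absent from the lexicon
    are dropped with a log entry, never raised: the task instructs scorers to
    exclude off-category items, not to abort.
    """
    rules = rules or NormalizationRules()
    seen: set[str] = set()
    out: list[str] = []
    for raw in record.responses:
        canon = canonical_form(raw)
        canon = rules.variant_map.get(canon, canon)
        if not canon:
            continue
        if rules.lexicon is not None and canon not in rules.lexicon:
            logger.info(
                "dropping off-lexicon response %r (participant %s)",
                raw,
                record.participant_id,
            )
            continue
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return FluencyRecord(record.participant_id, record.group, tuple(out))


@dataclass
class ResponseMatrix:
    """Binary participants x exemplars occurrence matrix for one group.

    Rows are participant ids, columns are canonical exemplar labels sorted
    lexicographically, cells are 1 iff the participant produced the exemplar.
    """

    data: pd.DataFrame
    group: str

    @property
    def participants(self) -> list[str]:
        return list(self.data.index)

    @property
    def exemplars(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_exemplars(self) -> int:
        return self.data.shape[1]

    def row_sums(self) -> np.ndarray:
        return self.data.to_numpy().sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.data.to_numpy().sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="participant_id")

    @classmethod
    def from_csv(cls, path: str | Path, group: str) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col="participant_id", dtype=None)
        df.index = df.index.astype(str)
        return cls(data=df.astype(np.int8), group=group)


def build_response_matrix(records: Sequence[FluencyRecord]) -> ResponseMatrix:
    """Tabulate normalised records of one group into a binary response matrix.

    Raises ``ValueError`` on mixed group labels: callers must split groups
    before tabulation.
    """
    if not records:
        raise ValueError("no records supplied")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError(
            f"records mix group labels {sorted(groups)}; split groups first"
        )
    columns = sorted(set().union(*(set(r.responses) for r in records)))
    ids = [r.participant_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids within a group")
    values = np.zeros((len(records), len(columns)), dtype=np.int8)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, rec in enumerate(records):
        for resp in rec.responses:
            values[i, col_index[resp]] = 1
    df = pd.DataFrame(values, index=ids, columns=columns)
    return ResponseMatrix(data=df, group=groups.pop())


def fluency_descriptives(mat_a: ResponseMatrix, mat_b: ResponseMatrix) -> dict:
    """Per-group fluency summaries: response counts and vocabulary overlap.

    ``distinct_exemplars`` counts columns actually produced (column sum >= 1);
    ``exclusive_exemplars`` counts exemplars one group produced that the other
    did not (set difference of produced column sets).
    """
    out: dict[str, dict] = {}
    produced_a = {c for c, s in zip(mat_a.exemplars, mat_a.column_sums()) if s >= 1}
    produced_b = {c for c, s in zip(mat_b.exemplars, mat_b.column_sums()) if s >= 1}
    for mat, produced, other in (
        (mat_a, produced_a, produced_b),
        (mat_b, produced_b, produced_a),
    ):
        rows = mat.row_sums().astype(float)
        out[mat.group] = {
            "n_participants": int(mat.n_participants),
            "mean_responses": float(rows.mean()),
            "sd_responses": float(rows.std(ddof=1)) if len(rows) > 1 else 0.0,
            "distinct_exemplars": len(produced),
            "exclusive_exemplars": len(produced - other),
        }
    return out


# ---------------------------------------------------------------------------
# Transcript and rules I/O (CSV/TSV, UTF-8)

_TRANSCRIPT_FIELDS = ["participant_id", "group", "rank", "response"]


def read_transcripts(path: str | Path, delimiter: str | None = None) -> list[FluencyRecord]:
    """Read a transcript CSV/TSV (`participant_id,group,rank,response`).

    Rows are ordered by production rank within participant; participant order
    follows first appearance in the file.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows: dict[str, list[tuple[int, str]]] = {}
    groups: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(_TRANSCRIPT_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"transcript missing columns: {sorted(missing)}")
        for row in reader:
            pid = row["participant_id"].strip()
            grp = row["group"].strip()
            if pid in groups and groups[pid] != grp:
                raise ValueError(f"participant {pid!r} appears under two groups")
            groups[pid] = grp
            rows.setdefault(pid, []).append((int(row["rank"]), row["response"]))
    records = []
    for pid, items in rows.items():
        items.sort(key=lambda t: t[0])
        records.append(FluencyRecord(pid, groups[pid], tuple(r for _, r in items)))
    return records


def write_transcripts(records: Iterable[FluencyRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRANSCRIPT_FIELDS)
        for rec in records:
            for rank, resp in enumerate(rec.responses, start=1):
                writer.writerow([rec.participant_id, rec.group, rank, resp])


def read_variant_map(path: str | Path) -> dict[str, str]:
    """Read a `variant,canonical` CSV into a variant map."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or []) < {"variant", "canonical"}:
            raise ValueError("variant map needs 'variant' and 'canonical' columns")
        for row in reader:
            out[row["variant"]] = row["canonical"]
    return out


def read_lexicon(path: str | Path) -> frozenset[str]:
    """Read a one-canonical-form-per-line lexicon file."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            canonical_form(line) for line in fh if line.strip() and not line.startswith("#")
        )


def split_groups(records: Sequence[FluencyRecord]) -> tuple[list[FluencyRecord], list[FluencyRecord]]:
    """Split a mixed record list into its two groups (lexicographic label order)."""
    labels = sorted({r.group for r in records})
    if len(labels) != 2:
        raise ValueError(f"expected exactly two group labels, found {labels}")
    a = [r for r in records if r.group == labels[0]]
    b = [r for r in records if r.group == labels[1]]
    return a, b
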