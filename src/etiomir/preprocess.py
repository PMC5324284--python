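"""Raw small-RNA FASTQ to clean, collapsed, contaminant-free tags.

Stages mirror standard small-RNA practice: quality filtration (no ambiguous
bases, mean Phred >= 20), 3' adapter trimming (leftmost match, minimum 6-nt
overlap, at most 1 mismatch per 10 aligned nucleotides), collapsing of
identical inserts into tags with per-sample counts, then removal of tags that
match a substring of any rRNA/tRNA/snRNA contaminant with at most one
mismatch over the full tag length.  Read conservation holds at every stage:
input reads = retained + the sum of per-reason rejections.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO


@dataclass
class Tally:
    """Per-reason rejection bookkeeping for one processing stage."""

    retained: int = 0
    rejected: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.retained + sum(self.rejected.values())


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Parse FASTQ into (id, sequence, phred qualities) tuples."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def quality_filter(
    reads: list[tuple[str, str, list[int]]], min_mean_phred: float = 20.0
) -> tuple[list[tuple[str, str]], Tally]:
    """Drop reads with ambiguous bases or low mean quality."""
    tally = Tally()
    kept = []
    for name, seq, qual in reads:
        if "N" in seq:
            tally.rejected["ambiguous"] += 1
        elif qual and sum(qual) / len(qual) < min_mean_phred:
            tally.rejected["low_quality"] += 1
        else:
            tally.retained += 1
            kept.append((name, seq))
    return kept, tally


def trim_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 6,
    length_window: tuple[int, int] = (18, 26),
) -> str | None:
    """Trim the 3' adapter; return the insert or None when rejected.

    The insert is the prefix before the leftmost adapter match.  A match at
    offset p aligns the adapter prefix against the read suffix over
    L = min(len(adapter), len(read)-p) positions, requires L >= min_overlap
    and at most floor(L/10) mismatches (i.e. <=1 mismatch per 10 aligned nt).
    Reads with no match, or with an insert outside the length window, are
    rejected.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter must be at least as long as the minimum overlap")
    n = len(sequence)
    for p in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - p)
        mismatches = sum(
            1 for a, b in zip(sequence[p : p + overlap], adapter[:overlap]) if a != b
        )
        if mismatches <= overlap // 10:
            insert = sequence[:p]
            if length_window[0] <= len(insert) <= length_window[1]:
                return insert
            return None
    return None


def trim_sample(
    reads: list[tuple[str, str]],
    adapter: str,
    min_overlap: int = 6,
    length_window: tuple[int, int] = (18, 26),
) -> tuple[list[str], Tally]:
    tally = Tally()
    inserts = []
    for _name, seq in reads:
        insert = trim_adapter(seq, adapter, min_overlap, length_window)
        if insert is None:
            # distinguish no-adapter from out-of-window for the tally
            has_match = (
                trim_adapter(seq, adapter, min_overlap, (0, len(seq))) is not None
            )
            tally.rejected["length" if has_match else "no_adapter"] += 1
        else:
            tally.retained += 1
            inserts.append(insert)
    return inserts, tally


def collapse_tags(per_sample_inserts: dict[str, list[str]]) -> pd.DataFrame:
    """Collapse identical inserts into tags with per-sample counts.

    Returns a DataFrame indexed by sequence with one integer column per
    sample (in the given order) plus a `length` column.
    """
    samples = list(per_sample_inserts)
    counters = {s: Counter(per_sample_inserts[s]) for s in samples}
    sequences = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else [])
    table = pd.DataFrame(
        {s: [counters[s].get(seq, 0) for seq in sequences] for s in samples},
        index=pd.Index(sequences, name="sequence"),
        dtype=int,
    )
    table.insert(0, "length", [len(s) for s in sequences])
    return table


class ContaminantIndex:
    """Lookup over all substrings of contaminant sequences in a length range.

    A query tag matches when it equals a substring exactly, or differs from
    one at a single position (implemented by hashing each substring once per
    masked position).
    """

    def __init__(
        self,
        records: list[tuple[str, str, str]],
        length_range: tuple[int, int] = (18, 26),
    ):
        # records: (class, identifier, sequence); classes disjoint by identifier
        ids = [cid for _cls, cid, _s in records]
        if len(ids) != len(set(ids)):
            raise ValueError("contaminant identifiers must be unique across classes")
        self.length_range = length_range
        self._exact: dict[str, str] = {}
        self._masked: dict[tuple[int, str], str] = {}
        for cls, _cid, seq in records:
            seq = seq.upper()
            for L in range(length_range[0], length_range[1] + 1):
                for i in range(0, len(seq) - L + 1):
                    sub = seq[i : i + L]
                    self._exact.setdefault(sub, cls)
                    for k in range(L):
                        key = (k, sub[:k] + sub[k + 1 :])
                        self._masked.setdefault(key, cls)

    def __len__(self) -> int:
        return len(self._exact)

    def lookup(self, tag: str) -> str | None:
        """Contaminant class for a tag (<=1 mismatch over full length), or None."""
        cls = self._exact.get(tag)
        if cls is not None:
            return cls
        for k in range(len(tag)):
            cls = self._masked.get((k, tag[:k] + tag[k + 1 :]))
            if cls is not None:
                return cls
        return None


def filter_contaminants(
    tags: pd.DataFrame, index: ContaminantIndex | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove contaminant tags; report per-class removed read/tag tallies."""
    if index is None or len(index) == 0:
        empty = pd.DataFrame(columns=["tags", "reads"])
        return tags, empty
    classes = [index.lookup(seq) for seq in tags.index]
    keep = [c is None for c in classes]
    sample_cols = [c for c in tags.columns if c != "length"]
    removed_rows = []
    for cls in ("rRNA", "tRNA", "snRNA"):
        mask = [c == cls for c in classes]
        removed_rows.append(
            {
                "class": cls,
                "tags": int(sum(mask)),
                "reads": int(tags.loc[mask, sample_cols].to_numpy().sum()),
            }
        )
    tally = pd.DataFrame(removed_rows).set_index("class")
    return tags.loc[keep], tally


def length_distribution(tags: pd.DataFrame) -> pd.DataFrame:
    """Per-length read and tag counts, per sample plus totals."""
    sample_cols = [c for c in tags.columns if c != "length"]
    if tags.empty:
        return pd.DataFrame(columns=["tags", *sample_cols, "reads"]).rename_axis("length")
    grouped = tags.groupby("length")
    reads = grouped[sample_cols].sum()
    out = reads.copy()
    out.insert(0, "tags", grouped.size())
    out["reads"] = reads.sum(axis=1)
    return out


def write_tag_table(path: str | Path, tags: pd.DataFrame):
    tags.to_csv(path, sep="\t")


def write_tag_fasta(path: str | Path, tags: pd.DataFrame):
    """Collapsed-read FASTA with miRDeep2-style `tag_<n>_x<total>` headers."""
    sample_cols = [c for c in tags.columns if c != "length"]
    with open(path, "w") as fh:
        for n, (seq, row) in enumerate(tags.iterrows(), start=1):
            total = int(row[sample_cols].sum())
            fh.write(f">tag_{n}_x{total}\n{seq}\n")
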