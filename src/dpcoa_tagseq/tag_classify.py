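"""Classification of basecalled direct-RNA reads as tagged or untagged.

A read is *tagged* when any run of ``k`` consecutive tag nucleotides
(default 12) occurs, as an exact match, entirely within the first
``window`` bases (default 50) of the read.  The tag is a short RNA
barcode ligated to noncanonically capped 5' ends, so its presence at
the 5' end of a basecalled read marks the molecule as cap-labelled.

Matching is exact at the seed level: basecall-error tolerance comes
from the many overlapping k-mers of the tag (a 40-nt tag offers 29
distinct 12-mer seeds), not from approximate matching.  On a seed hit
the match is extended greedily to the right for trimming purposes.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "TagSpec",
    "TagCall",
    "FastqRecord",
    "SequenceFormatError",
    "FastqFormatError",
    "normalize_sequence",
    "find_tag_match",
    "classify_reads",
    "classify_fastq",
    "trim_tag",
    "read_fastq",
    "write_fastq",
    "load_tag_sequence",
]


class SequenceFormatError(ValueError):
    """A nucleotide sequence contains characters outside {A,C,G,T,N,U}."""


class FastqFormatError(ValueError):
    """A FASTQ stream could not be parsed."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide sequence and convert U to T.

    Direct-RNA basecallers may emit U; all downstream matching works in
    the DNA alphabet.  Characters outside {A,C,G,T,N} after conversion
    are rejected.

    Raises
    ------
    SequenceFormatError
        If the sequence is empty or contains an illegal character; the
        message names the 0-based offending position.
    """
    if not seq:
        raise SequenceFormatError("empty sequence")
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in "ACGTN":
            raise SequenceFormatError(
                f"illegal character {ch!r} at position {pos}"
            )
    return out


@dataclass(frozen=True)
class TagSpec:
    """The tag sequence plus the (k, window) classification parameters.

    Parameters
    ----------
    tag_sequence
        Tag barcode, 5'->3'.  Stored internally in the DNA alphabet
        (U converted to T, uppercased).
    k
        Minimum exact consecutive match length (default 12).
    window
        5' search window in bases; the whole seed must fall within the
        first ``window`` bases of the read (default 50).
    """

    tag_sequence: str
    k: int = 12
    window: int = 50

    def __post_init__(self) -> None:
        norm = normalize_sequence(self.tag_sequence)
        if "N" in norm:
            raise SequenceFormatError("tag sequence may not contain N")
        object.__setattr__(self, "tag_sequence", norm)
        if not (1 <= self.k <= self.window):
            raise ValueError(f"require 1 <= k <= window, got k={self.k}, window={self.window}")
        if len(norm) < self.k:
            raise ValueError(
                f"tag length {len(norm)} shorter than match length k={self.k}"
            )

    @cached_property
    def seed_index(self) -> dict[str, int]:
        """Map each k-mer of the tag to its smallest tag offset."""
        idx: dict[str, int] = {}
        tag = self.tag_sequence
        for j in range(len(tag) - self.k + 1):
            idx.setdefault(tag[j : j + self.k], j)
        return idx


@dataclass(frozen=True)
class TagCall:
    """Per-read classification outcome.

    ``match_start``/``match_end`` are 0-based half-open read coordinates
    of the maximal greedily extended match; ``tag_offset`` is the
    0-based offset of the seed within the tag.  All three are ``None``
    for untagged reads.  The seed lies entirely within the search
    window; the extension may run past it.
    """

    read_id: str
    tagged: bool
    match_start: int | None = None
    match_end: int | None = None
    tag_offset: int | None = None

    def __post_init__(self) -> None:
        coords = (self.match_start, self.match_end, self.tag_offset)
        if self.tagged and any(c is None for c in coords):
            raise ValueError("tagged call requires match coordinates")
        if not self.tagged and any(c is not None for c in coords):
            raise ValueError("untagged call must not carry match coordinates")


@dataclass
class FastqRecord:
    """A minimal FASTQ record (id, sequence, quality string)."""

    read_id: str
    sequence: str
    quality: str
    comment: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"read {self.read_id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


def _find_match_in_seq(seq: str, spec: TagSpec, seed_index: dict[str, int]):
    """Core seed search over one orientation; returns coords or None."""
    k = spec.k
    tag = spec.tag_sequence
    last_start = min(len(seq), spec.window) - k
    for i in range(last_start + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = seed_index.get(kmer)
        if j is None:
            continue
        # greedy rightward extension while read and tag agree
        e, t = i + k, j + k
        n, m = len(seq), len(tag)
        while e < n and t < m and seq[e] == tag[t] and seq[e] != "N":
            e += 1
            t += 1
        return i, e, j
    return None


def find_tag_match(
    read_seq: str,
    spec: TagSpec,
    *,
    both_orientations: bool = False,
    _seed_index: dict[str, int] | None = None,
) -> TagCall | None:
    """Locate the leftmost exact k-mer tag seed in the 5' window.

    Returns the coordinate fields of a :class:`TagCall` (with an empty
    ``read_id``) when the read is tagged, or ``None`` otherwise.  The
    search is forward-orientation only by default: nanopore direct RNA
    reads are reported 5'->3' in the sense of the transcript.  With
    ``both_orientations=True`` the reverse complement of the tag is
    also searched (coordinates still refer to the read as given).
    Reads shorter than ``k`` are untagged by definition; reads shorter
    than the window are searched over their full length.  ``N`` bases
    never match any tag base.
    """
    seq = read_seq.upper().replace("U", "T")
    if len(seq) < spec.k:
        return None
    idx = _seed_index if _seed_index is not None else spec.seed_index
    hit = _find_match_in_seq(seq, spec, idx)
    if hit is None and both_orientations:
        rc_spec = replace(
            spec, tag_sequence=spec.tag_sequence.translate(_COMPLEMENT)[::-1]
        )
        hit = _find_match_in_seq(seq, rc_spec, rc_spec.seed_index)
    if hit is None:
        return None
    start, end, tag_offset = hit
    return TagCall(
        read_id="", tagged=True, match_start=start, match_end=end, tag_offset=tag_offset
    )


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records (plain or gzip) via pysam.

    Raises :class:`FastqFormatError` naming the record index when the
    stream is malformed.
    """
    index = 0
    try:
        with pysam.FastxFile(str(path)) as fx:
            for entry in fx:
                if entry.quality is None:
                    raise FastqFormatError(
                        f"record {index} ({entry.name!r}) has no quality string "
                        "(is this FASTA?)"
                    )
                yield FastqRecord(
                    read_id=entry.name,
                    sequence=entry.sequence,
                    quality=entry.quality,
                    comment=entry.comment,
                )
                index += 1
    except FastqFormatError:
        raise
    except (OSError, ValueError) as exc:
        raise FastqFormatError(f"malformed FASTQ near record {index}: {exc}") from exc


def _open_text_maybe_gzip(path: str | Path) -> IO[str]:
    """Open a text stream for writing; gzip (mtime=0, reproducible) for .gz."""
    import io

    path = Path(path)
    if path.suffix == ".gz":
        gz = gzip.GzipFile(str(path), "wb", mtime=0)
        return io.TextIOWrapper(gz)
    return open(path, "w")


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write FASTQ records to ``path`` (gzipped when it ends in .gz)."""
    n = 0
    with _open_text_maybe_gzip(path) as fh:
        for rec in records:
            header = rec.read_id if rec.comment is None else f"{rec.read_id} {rec.comment}"
            fh.write(f"@{header}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def load_tag_sequence(source: str | Path) -> str:
    """Read a tag sequence from a single-record FASTA file or a literal.

    Anything that exists on disk is parsed as FASTA; otherwise the
    string itself is taken as the sequence.
    """
    p = Path(str(source))
    if p.exists():
        with pysam.FastxFile(str(p)) as fx:
            entries = [e.sequence for e in fx]
        if len(entries) != 1:
            raise SequenceFormatError(
                f"tag FASTA {p} must contain exactly one record, found {len(entries)}"
            )
        return normalize_sequence(entries[0])
    return normalize_sequence(str(source))


def trim_tag(read: FastqRecord, call: TagCall) -> FastqRecord:
    """Remove the matched tag bases [0, match_end) from a tagged read.

    Qualities are trimmed in lockstep.  Untagged reads are returned
    unchanged.  Trimming the whole read is an error (the alignment
    stage needs a non-empty sequence).
    """
    if not call.tagged:
        return read
    end = call.match_end
    assert end is not None
    if end >= len(read.sequence):
        raise ValueError(
            f"read {read.read_id!r}: trimming [0, {end}) would leave an empty sequence"
        )
    return FastqRecord(
        read_id=read.read_id,
        sequence=read.sequence[end:],
        quality=read.quality[end:],
        comment=read.comment,
    )


def classify_reads(
    reads: Iterable[FastqRecord],
    spec: TagSpec,
    *,
    trim: bool = False,
    both_orientations: bool = False,
) -> Iterator[tuple[FastqRecord, TagCall]]:
    """Classify an iterable of FASTQ records against a tag.

    Yields ``(record, call)`` pairs in input order; when ``trim`` is
    set, tagged records are returned with the matched tag bases
    removed (a tagged read whose match spans the whole sequence is
    left untrimmed with a warning rather than emptied).  Duplicate
    read ids are kept, with a warning.
    """
    idx = spec.seed_index
    seen: set[str] = set()
    for rec in reads:
        if rec.read_id in seen:
            warnings.warn(f"duplicate read id {rec.read_id!r}; keeping both")
        seen.add(rec.read_id)
        hit = find_tag_match(
            rec.sequence, spec, both_orientations=both_orientations, _seed_index=idx
        )
        if hit is None:
            call = TagCall(read_id=rec.read_id, tagged=False)
        else:
            call = replace(hit, read_id=rec.read_id)
            if trim:
                try:
                    rec = trim_tag(rec, call)
                except ValueError:
                    logger.warning(
                        "read %s: match spans entire read; left untrimmed", rec.read_id
                    )
        yield rec, call


def classify_fastq(
    reads_path: str | Path,
    spec: TagSpec,
    out_prefix: str | Path,
    *,
    trim: bool = False,
    both_orientations: bool = False,
    gzip_output: bool = True,
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Classify a FASTQ file into tagged/untagged streams plus a call table.

    Writes ``<prefix>.tagged.fastq[.gz]``, ``<prefix>.untagged.fastq[.gz]``
    and returns the TagCall table as a DataFrame with columns
    read_id, tagged, match_start, match_end, tag_offset.  Every input
    read appears in exactly one output stream.
    """
    import pandas as pd

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    tagged_path = Path(f"{out_prefix}.tagged{suffix}")
    untagged_path = Path(f"{out_prefix}.untagged{suffix}")
    rows: list[dict] = []
    with _open_text_maybe_gzip(tagged_path) as ft, _open_text_maybe_gzip(
        untagged_path
    ) as fu:
        for rec, call in classify_reads(
            read_fastq(reads_path), spec, trim=trim, both_orientations=both_orientations
        ):
            fh = ft if call.tagged else fu
            header = rec.read_id if rec.comment is None else f"{rec.read_id} {rec.comment}"
            fh.write(f"@{header}\n{rec.sequence}\n+\n{rec.quality}\n")
            rows.append(
                {
                    "read_id": call.read_id,
                    "tagged": call.tagged,
                    "match_start": call.match_start,
                    "match_end": call.match_end,
                    "tag_offset": call.tag_offset,
                }
            )
    return pd.DataFrame(
        rows, columns=["read_id", "tagged", "match_start", "match_end", "tag_offset"]
    )
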