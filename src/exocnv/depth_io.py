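"""Exon targets, per-base depth extraction, and model-input encoding.

The classifier consumes one standardized per-base read-depth vector per exon
target.  Vectors are left-padded with a ``-1`` sentinel to a fixed maximum
length; a boolean mask records which positions carry real signal so that
downstream attention can ignore the padding.  Coordinates are BED-style
0-based half-open throughout; per-base depth tables use 1-based positions
(the dialect emitted by samtools/sambamba depth) and are converted on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEL = "DEL"
DUP = "DUP"
NOCALL = "NOCALL"
LABELS = (DEL, DUP, NOCALL)
LABEL_TO_INT = {DEL: 0, DUP: 1, NOCALL: 2}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}

#: number of chromosomes with a classification token (1..22, X=23, Y=24)
N_CHROMOSOMES = 24

PAD_SENTINEL = -1.0


def chrom_name_to_index(name: str) -> int | None:
    """Map ``chr1``/``1``/``chrX`` style names to the 1..24 index.

    Returns ``None`` for contigs outside the 24 canonical chromosomes
    (chrM, alt/decoy contigs, ...), which callers skip.
    """
    token = name.strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    if token in ("X", "x"):
        return 23
    if token in ("Y", "y"):
        return 24
    try:
        idx = int(token)
    except ValueError:
        return None
    return idx if 1 <= idx <= 22 else None


def chrom_index_to_name(idx: int) -> str:
    if idx == 23:
        return "chrX"
    if idx == 24:
        return "chrY"
    return f"chr{idx}"


@dataclass(frozen=True, order=True)
class ExonTarget:
    """One capture interval: chromosome index 1..24, 0-based half-open coords."""

    chrom_index: int
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.chrom_index <= N_CHROMOSOMES:
            raise ValueError(f"chrom_index {self.chrom_index} outside 1..{N_CHROMOSOMES}")
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class StandardizationStats:
    """Global read-depth mean/sd of the training corpus; reused at inference."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("standardization sd must be > 0")

    @property
    def key(self) -> str:
        payload = json.dumps({"mean": float(self.mean), "sd": float(self.sd)})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EncodedExon:
    """Standardized, left-padded, masked depth vector ready for the model.

    ``depth`` has fixed length ``max_len``; the first ``max_len - n_real``
    entries are the pad sentinel -1 and masked out, the trailing ``n_real``
    entries are standardized real depth values.
    """

    depth: np.ndarray
    mask: np.ndarray
    target: ExonTarget
    n_real: int
    stats_key: str = ""

    def __post_init__(self) -> None:
        n = self.depth.shape[0]
        if self.mask.shape[0] != n:
            raise ValueError("depth/mask length mismatch")
        if not 1 <= self.n_real <= n:
            raise ValueError("n_real out of range")
        if int(self.mask.sum()) != self.n_real or self.mask[-self.n_real :].sum() != self.n_real:
            raise ValueError("mask must have exactly n_real trailing True values")


def load_exon_targets(bed_source: str | Path | Iterable[str]) -> list[ExonTarget]:
    """Parse a BED of exon targets, sorted by (chromosome, start).

    Lines on unrecognized contigs are skipped and counted in the log;
    malformed lines raise with their line number.
    """
    if isinstance(bed_source, (str, Path)):
        lines: Iterable[str] = Path(bed_source).read_text().splitlines()
    else:
        lines = bed_source
    targets: list[ExonTarget] = []
    skipped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: expected >=3 tab-separated fields")
        idx = chrom_name_to_index(fields[0])
        if idx is None:
            skipped += 1
            continue
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
        try:
            targets.append(ExonTarget(idx, start, end, name))
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: {exc}") from exc
    if skipped:
        logger.info("skipped %d target(s) on non-canonical contigs", skipped)
    targets.sort(key=lambda t: (t.chrom_index, t.start, t.end))
    return targets


def read_depth_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load a per-base depth TSV (chrom, 1-based position, depth)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(
            source, sep="\t", header=None, names=["chrom", "pos", "depth"], comment="#"
        )
    df.columns = ["chrom", "pos", "depth"]
    if (df["depth"] < 0).any():
        bad = df.loc[df["depth"] < 0].iloc[0]
        raise ValueError(f"negative depth at {bad['chrom']}:{bad['pos']}")
    return df


def extract_depth_vectors(
    depth_table: str | Path | pd.DataFrame,
    targets: Sequence[ExonTarget],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Per-target raw depth vectors from a per-base depth table.

    Returns ``(vectors, no_depth_ids)``: one vector of length ``end - start``
    per target (0 where the table has no row), and the ids of targets whose
    vector is entirely zero.  Table positions are 1-based; rows outside every
    target are ignored.
    """
    df = read_depth_table(depth_table)
    chrom_idx = df["chrom"].map(lambda c: chrom_name_to_index(str(c)))
    df = df.assign(_ci=chrom_idx).dropna(subset=["_ci"])

    by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ci, grp in df.groupby("_ci"):
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        order = np.argsort(pos0, kind="stable")
        by_chrom[int(ci)] = (pos0[order], grp["depth"].to_numpy(dtype=np.float64)[order])

    vectors: dict[str, np.ndarray] = {}
    no_depth: list[str] = []
    for t in targets:
        vec = np.zeros(t.length, dtype=np.float64)
        if t.chrom_index in by_chrom:
            pos, dep = by_chrom[t.chrom_index]
            lo = np.searchsorted(pos, t.start, side="left")
            hi = np.searchsorted(pos, t.end, side="left")
            vec[pos[lo:hi] - t.start] = dep[lo:hi]
        vectors[t.id] = vec
        if not vec.any():
            no_depth.append(t.id)
    if no_depth:
        logger.info("%d/%d targets have no read depth", len(no_depth), len(targets))
    return vectors, no_depth


def compute_standardization_stats(
    vectors: Mapping[str, np.ndarray] | Iterable[np.ndarray],
) -> StandardizationStats:
    """Global mean/sd over every per-base depth value of a training corpus.

    Zero-depth bases inside covered targets contribute to the statistics.
    """
    arrays = list(vectors.values()) if isinstance(vectors, Mapping) else list(vectors)
    if not arrays:
        raise ValueError("no depth vectors given")
    flat = np.concatenate([np.asarray(a, dtype=np.float64) for a in arrays])
    sd = float(flat.std())
    if sd == 0:
        raise ValueError("constant depth corpus: sd = 0")
    return StandardizationStats(mean=float(flat.mean()), sd=sd)


def standardize_and_pad(
    raw_vector: np.ndarray,
    stats: StandardizationStats,
    target: ExonTarget,
    max_len: int = 1000,
) -> EncodedExon | None:
    """Standardize a raw depth vector and left-pad it to ``max_len``.

    Vectors longer than ``max_len`` keep only their nonzero-depth positions
    (genomic order preserved); if those still number >= ``max_len``, or none
    remain, the exon is not directly encodable and ``None`` is returned (the
    caller routes it through the nearest-neighbour vote instead).
    """
    raw = np.asarray(raw_vector, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("empty depth vector")
    if raw.size > max_len:
        raw = raw[raw != 0]
        if raw.size == 0 or raw.size >= max_len:
            return None
    z = (raw - stats.mean) / stats.sd
    n_real = z.size
    depth = np.full(max_len, PAD_SENTINEL, dtype=np.float32)
    depth[max_len - n_real :] = z.astype(np.float32)
    mask = np.zeros(max_len, dtype=bool)
    mask[max_len - n_real :] = True
    return EncodedExon(depth=depth, mask=mask, target=target, n_real=n_real, stats_key=stats.key)


def encode_sample(
    depth_table: str | Path | pd.DataFrame,
    targets: Sequence[ExonTarget],
    stats: StandardizationStats,
    max_len: int = 1000,
) -> tuple[list[EncodedExon], list[ExonTarget]]:
    """Full encoding pipeline: extraction, standardization, padding.

    Returns the encodable exons plus the targets left for imputation
    (no depth, or too long to encode).
    """
    vectors, no_depth_ids = extract_depth_vectors(depth_table, targets)
    no_depth = set(no_depth_ids)
    encoded: list[EncodedExon] = []
    leftover: list[ExonTarget] = []
    for t in targets:
        if t.id in no_depth:
            leftover.append(t)
            continue
        enc = standardize_and_pad(vectors[t.id], stats, t, max_len=max_len)
        if enc is None:
            leftover.append(t)
        else:
            encoded.append(enc)
    return encoded, leftover


# ---------------------------------------------------------------------------
# call / truth file round trip


@dataclass(frozen=True)
class TruthCall:
    """A truth interval: DEL/DUP label or an integer copy number."""

    chrom_index: int
    start: int
    end: int
    call: str | None = None
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if (self.call is None) == (self.copy_number is None):
            raise ValueError("exactly one of call / copy_number must be set")
        if self.call is not None and self.call not in (DEL, DUP):
            raise ValueError(f"unknown truth call token {self.call!r}")


def read_truth_bed(source: str | Path | Iterable[str]) -> list[TruthCall]:
    """BED-like truth file: chrom, start, end, {DEL|DUP|integer CN}."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    out: list[TruthCall] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"truth line {lineno}: expected 4 fields")
        idx = chrom_name_to_index(fields[0])
        if idx is None:
            continue
        start, end = int(fields[1]), int(fields[2])
        token = fields[3].strip()
        if token in (DEL, DUP):
            out.append(TruthCall(idx, start, end, call=token))
        else:
            try:
                cn = int(token)
            except ValueError as exc:
                raise ValueError(f"truth line {lineno}: unknown call token {token!r}") from exc
            out.append(TruthCall(idx, start, end, copy_number=cn))
    out.sort(key=lambda c: (c.chrom_index, c.start, c.end))
    return out


CALL_FILE_COLUMNS = ["chrom", "start", "end", "id", "call", "p_del", "p_dup", "p_nocall", "imputed"]


def write_call_file(records, sink: str | Path) -> None:
    """Write per-exon call records as a TSV (see :data:`CALL_FILE_COLUMNS`)."""
    rows = []
    for r in records:
        p = r.probs
        rows.append(
            {
                "chrom": chrom_index_to_name(r.target.chrom_index),
                "start": r.target.start,
                "end": r.target.end,
                "id": r.target.id,
                "call": r.call,
                "p_del": "" if p is None else f"{p.p_del:.6g}",
                "p_dup": "" if p is None else f"{p.p_dup:.6g}",
                "p_nocall": "" if p is None else f"{p.p_nocall:.6g}",
                "imputed": int(r.imputed),
            }
        )
    pd.DataFrame(rows, columns=CALL_FILE_COLUMNS).to_csv(sink, sep="\t", index=False)


def read_call_file(source: str | Path):
    """Inverse of :func:`write_call_file`; returns a list of CallRecord."""
    from .calling import CallRecord  # local import: calling depends on this module
    from .encoder_model import ClassProbabilities

    df = pd.read_csv(source, sep="\t", dtype={"imputed": "Int64"})
    records = []
    for row in df.itertuples(index=False):
        idx = chrom_name_to_index(str(row.chrom))
        if idx is None:
            raise ValueError(f"unknown chromosome {row.chrom!r} in call file")
        if row.call not in LABELS:
            raise ValueError(f"unknown call token {row.call!r}")
        target = ExonTarget(idx, int(row.start), int(row.end), str(row.id))
        probs = None
        if not (pd.isna(row.p_del) or row.p_del == ""):
            probs = ClassProbabilities(float(row.p_del), float(row.p_dup), float(row.p_nocall))
        records.append(
            CallRecord(target=target, call=str(row.call), probs=probs, imputed=bool(row.imputed))
        )
    return records


def write_targets_bed(targets: Sequence[ExonTarget], sink: str | Path) -> None:
    with open(sink, "w") as fh:
        for t in targets:
            fh.write(f"{chrom_index_to_name(t.chrom_index)}\t{t.start}\t{t.end}\t{t.id}\n")


def write_truth_bed(calls: Sequence[TruthCall], sink: str | Path) -> None:
    with open(sink, "w") as fh:
        for c in calls:
            token = c.call if c.call is not None else str(c.copy_number)
            fh.write(f"{chrom_index_to_name(c.chrom_index)}\t{c.start}\t{c.end}\t{token}\n")


def write_depth_table(df: pd.DataFrame, sink: str | Path) -> None:
    df.to_csv(sink, sep="\t", header=False, index=False)
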