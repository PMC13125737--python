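"""Data model and I/O for the promoter-methylation pipeline.

Containers for per-CpG pyrosequencing methylation matrices, qPCR ΔCt
expression tables, JASPAR position frequency matrices, and qMSP Ct tables,
plus the sequence utilities (CpG site and CpG island detection) they rely on.

Conventions
-----------
* Coordinates are 0-based, half-open everywhere internally; 1-based
  inclusive labels (``CpG_1`` ...) appear only in human-readable reports.
* A CpG site is identified by the position of its C on the supplied (+)
  orientation; methylation is treated as strand-symmetric.
* Tables are UTF-8 TSV with ``NA`` for missing values.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PromoterRegion",
    "MethylationMatrix",
    "ExpressionTable",
    "PFMRecord",
    "QmspTable",
    "ValidationError",
    "FormatError",
    "find_cpg_sites",
    "find_cpg_islands",
    "compute_dct",
    "read_methylation_table",
    "write_methylation_table",
    "read_expression_table",
    "write_expression_table",
    "read_qmsp_table",
    "write_qmsp_table",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta_regions",
    "write_fasta_regions",
    "write_report",
    "read_report",
    "hits_to_bed",
    "cpg_label",
    "NA_TOKEN",
]

NA_TOKEN = "NA"

_DNA_ALPHABET = set("ACGTN")
_BASES = "ACGT"


class ValidationError(ValueError):
    """A table or record violates a data-model invariant."""


class FormatError(ValueError):
    """External file content cannot be parsed."""


def cpg_label(i: int) -> str:
    """1-based display label for the i-th CpG site (0-based index)."""
    return f"CpG_{i + 1}"


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def find_cpg_sites(sequence: str) -> list[int]:
    """Return 0-based positions p with ``sequence[p:p+2] == "CG"``.

    Overlap-aware (``CGCG`` yields [0, 2]); ``N`` never matches; an empty
    sequence yields an empty list.
    """
    seq = sequence.upper()
    return [m.start() for m in re.finditer(r"(?=CG)", seq)]


def find_cpg_islands(
    sequence: str,
    *,
    min_len: int = 200,
    gc_min: float = 0.5,
    obs_exp_min: float = 0.6,
    window: int = 200,
) -> list[tuple[int, int]]:
    """Detect CpG islands with the standard sliding-window criterion.

    Every window of length ``window`` is tested for GC fraction >= ``gc_min``
    and CpG observed/expected ratio >= ``obs_exp_min`` (obs/exp =
    n_CpG * window / (n_C * n_G)).  Passing windows are merged into maximal
    intervals and intervals shorter than ``min_len`` are dropped.  Returns
    sorted, non-overlapping half-open intervals.

    The conventional thresholds (200 nt, GC >= 0.5, obs/exp >= 0.6) are the
    defaults; a stricter GC >= 0.6 "literal" variant of the textbook CGI
    definition can be requested by passing ``gc_min=0.6``.
    """
    if min_len <= 0 or window <= 0 or window > min_len:
        raise ValueError("require 0 < window <= min_len")
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cpg[:-1] = is_c[:-1] & (arr[1:] == ord("G"))

    def _winsum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[window:] - c[:-window]

    c_cnt = _winsum(is_c)
    g_cnt = _winsum(is_g)
    # CpG dinucleotides fully inside the window: starts in [i, i+window-1)
    cp = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(n - window + 1)
    cpg_cnt = cp[starts + window - 1] - cp[starts]

    gc_frac = (c_cnt + g_cnt) / window
    expected = c_cnt * g_cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(expected > 0, cpg_cnt * window / np.where(expected > 0, expected, 1), 0.0)
    passing = (gc_frac >= gc_min) & (obs_exp >= obs_exp_min)

    intervals: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(passing):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            intervals.append((start, i - 1 + window))
            start = None
    if start is not None:
        intervals.append((start, len(passing) - 1 + window))

    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len]


def compute_dct(ct_target: float, ct_reference: float) -> float:
    """ΔCt = Ct(target) − Ct(reference); lower ΔCt means higher abundance.

    Missing (NaN) inputs propagate to a missing ΔCt.
    """
    if ct_target is None or ct_reference is None:
        return float("nan")
    return float(ct_target) - float(ct_reference)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PromoterRegion:
    """A named promoter sequence with its annotated CpG sites.

    ``cpg_positions`` holds the 0-based offset of the C of every CpG
    dinucleotide on the given (+) orientation; it is computed from the
    sequence when not supplied.  ``strand`` annotates the direction of the
    transcript relative to the sequence (an antisense transcript is ``-``);
    it does not change coordinates.
    """

    name: str
    sequence: str
    strand: str = "+"
    tss_offset: int | None = None
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValidationError(f"region {self.name!r}: non-DNA characters {sorted(bad)}")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"region {self.name!r}: strand must be '+' or '-'")
        if not self.cpg_positions:
            self.cpg_positions = find_cpg_sites(self.sequence)
        else:
            prev = -1
            for p in self.cpg_positions:
                if not (0 <= p < len(self.sequence) - 1):
                    raise ValidationError(f"region {self.name!r}: CpG position {p} out of bounds")
                if self.sequence[p : p + 2] != "CG":
                    raise ValidationError(f"region {self.name!r}: position {p} is not a CpG")
                if p <= prev:
                    raise ValidationError(f"region {self.name!r}: CpG positions not strictly increasing")
                prev = p

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def cpg_labels(self) -> list[str]:
        return [cpg_label(i) for i in range(self.n_cpgs)]


@dataclass
class MethylationMatrix:
    """Replicated per-CpG percent methylation for a panel of samples.

    ``data`` is a DataFrame with a (sample, replicate) MultiIndex and one
    column per CpG label; values are percent in [0, 100], NaN for missing.
    """

    data: pd.DataFrame
    region: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.names != ["sample", "replicate"]:
            raise ValidationError("MethylationMatrix.data needs a (sample, replicate) MultiIndex")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate (sample, replicate) row: {dup}")
        vals = self.data.to_numpy(dtype=float)
        bad = np.argwhere((vals < 0) | (vals > 100))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"methylation percent out of [0, 100] at sample={self.data.index[r][0]!r} "
                f"replicate={self.data.index[r][1]!r} column={self.data.columns[c]!r}: {vals[r, c]}"
            )
        counts = self.data.groupby(level="sample", sort=False).size()
        if (counts < 1).any():
            raise ValidationError("every sample needs at least one replicate")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values("sample")))

    @property
    def cpg_labels(self) -> list[str]:
        return list(self.data.columns)

    def attach_region(self, region: PromoterRegion) -> None:
        if len(self.cpg_labels) != region.n_cpgs:
            raise ValidationError(
                f"matrix has {len(self.cpg_labels)} CpG columns but region "
                f"{region.name!r} has {region.n_cpgs} CpG sites"
            )
        self.region = region.name

    def aggregate(self, stat: str = "median") -> pd.DataFrame:
        """Collapse replicates per (sample, CpG); a cell missing in more than
        half the replicates of a sample is reported missing."""
        if stat not in {"median", "mean"}:
            raise ValueError("stat must be 'median' or 'mean'")
        grouped = self.data.groupby(level="sample", sort=False)
        agg = grouped.median() if stat == "median" else grouped.mean()
        n_rep = grouped.size()
        n_obs = grouped.count()
        too_sparse = n_obs.lt(n_rep / 2.0, axis=0)
        return agg.mask(too_sparse)


@dataclass
class ExpressionTable:
    """ΔCt values per (sample, replicate) × transcript.

    Each transcript carries the reference gene used for its normalisation
    (e.g. GAPDH for coding transcripts, U6 for a lncRNA); ΔCt values from
    different normalisers are never mixed arithmetically across transcripts.
    """

    data: pd.DataFrame
    reference_genes: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.names != ["sample", "replicate"]:
            raise ValidationError("ExpressionTable.data needs a (sample, replicate) MultiIndex")
        missing_ref = [t for t in self.data.columns if not self.reference_genes.get(t)]
        if missing_ref:
            raise ValidationError(f"transcripts without a reference gene: {missing_ref}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("ΔCt values must be finite where present")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values("sample")))

    @property
    def transcripts(self) -> list[str]:
        return list(self.data.columns)

    def aggregate(self, stat: str = "median") -> pd.DataFrame:
        grouped = self.data.groupby(level="sample", sort=False)
        return grouped.median() if stat == "median" else grouped.mean()


@dataclass
class PFMRecord:
    """A JASPAR position frequency matrix: base counts per motif column."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # 4 × w, rows A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError(f"motif {self.motif_id!r}: counts must be 4 × w")
        if (self.counts < 0).any():
            raise ValidationError(f"motif {self.motif_id!r}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValidationError(f"motif {self.motif_id!r}: a column has no positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


_QMSP_GROUPS = {"case_tissue", "case_plasma", "control_smoker", "control_nonsmoker", "C_plus", "C_minus"}


@dataclass
class QmspTable:
    """qMSP Ct table: methylation-specific target Ct and input-control Ct.

    ``data`` is indexed by sample with columns group, ct_target,
    ct_reference, dct (= ct_target − ct_reference).  Non-detection is a
    missing Ct.  Exactly one ``C_minus`` row is required before calling.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "ct_target", "ct_reference"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"qMSP table missing columns: {sorted(missing)}")
        unknown = set(self.data["group"]) - _QMSP_GROUPS
        if unknown:
            raise ValidationError(f"unknown qMSP group labels: {sorted(unknown)}")
        for col in ("ct_target", "ct_reference"):
            v = self.data[col].to_numpy(dtype=float)
            if ((v <= 0) & ~np.isnan(v)).any() or np.isinf(v).any():
                raise ValidationError(f"{col}: Ct values must be positive and finite where detected")
        if "dct" not in self.data.columns:
            self.data = self.data.assign(dct=self.data["ct_target"] - self.data["ct_reference"])

    @property
    def background_dct(self) -> float:
        cminus = self.data[self.data["group"] == "C_minus"]
        if len(cminus) != 1:
            raise ValidationError(f"exactly one C_minus row required, found {len(cminus)}")
        dct = float(cminus["dct"].iloc[0])
        if np.isnan(dct):
            raise ValidationError("C_minus row has no ΔCt (missing Ct)")
        return dct


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(text: str, **kw) -> pd.DataFrame:
    return pd.read_csv(
        io.StringIO(text), sep="\t", na_values=[NA_TOKEN], keep_default_na=False, comment="#", **kw
    )


def _to_tsv(df: pd.DataFrame, index: bool = False) -> str:
    return df.to_csv(sep="\t", na_rep=NA_TOKEN, index=index)


def read_methylation_table(text: str, region: str | None = None) -> MethylationMatrix:
    """Parse a wide methylation TSV: columns ``sample``, ``replicate``,
    then one percent column per CpG label."""
    df = _read_tsv(text)
    for col in ("sample", "replicate"):
        if col not in df.columns:
            raise FormatError(f"methylation table missing {col!r} column")
    df = df.set_index(["sample", "replicate"])
    df = df.astype(float)
    return MethylationMatrix(data=df, region=region)


def write_methylation_table(matrix: MethylationMatrix) -> str:
    return _to_tsv(matrix.data.reset_index())


def read_expression_table(text: str) -> ExpressionTable:
    """Parse an expression TSV whose ``# reference_gene`` comment lines map
    each transcript to its normaliser."""
    refs: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("# reference_gene"):
            parts = line.lstrip("# ").split("\t")
            if len(parts) == 3:
                refs[parts[1]] = parts[2]
    df = _read_tsv(text)
    for col in ("sample", "replicate"):
        if col not in df.columns:
            raise FormatError(f"expression table missing {col!r} column")
    df = df.set_index(["sample", "replicate"]).astype(float)
    for t in df.columns:
        refs.setdefault(t, "")
    return ExpressionTable(data=df, reference_genes=refs)


def write_expression_table(table: ExpressionTable) -> str:
    header = "".join(
        f"# reference_gene\t{t}\t{table.reference_genes[t]}\n" for t in table.transcripts
    )
    return header + _to_tsv(table.data.reset_index())


def read_qmsp_table(text: str) -> QmspTable:
    df = _read_tsv(text)
    if "sample" not in df.columns:
        raise FormatError("qMSP table missing 'sample' column")
    df = df.set_index("sample")
    return QmspTable(data=df)


def write_qmsp_table(table: QmspTable) -> str:
    return _to_tsv(table.data.reset_index())


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_jaspar_pfm(text: str) -> list[PFMRecord]:
    """Parse JASPAR PFM records (">" headers, four base rows in A,C,G,T order).

    Accepts both circulating dialects: bracketed labelled rows
    (``A [ 4 0 ]``) and matrix-only rows of numbers.
    """
    records: list[PFMRecord] = []
    header: str | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def _flush() -> None:
        nonlocal header, rows
        if header is None and not rows:
            return
        if header is None:
            raise FormatError("PFM rows before any '>' header")
        if len(rows) != 4:
            raise FormatError(f"record {header!r}: expected 4 base rows, got {len(rows)}")
        labels = [lab for lab, _ in rows]
        if all(lab is not None for lab in labels):
            order = {lab: vals for lab, vals in rows}
            if set(order) != set(_BASES):
                raise FormatError(f"record {header!r}: unknown/duplicate base row labels {labels}")
            mat = [order[b] for b in _BASES]
        elif all(lab is None for lab in labels):
            mat = [vals for _, vals in rows]
        else:
            raise FormatError(f"record {header!r}: mixed labelled and unlabelled rows")
        widths = {len(r) for r in mat}
        if len(widths) != 1:
            raise FormatError(f"record {header!r}: mismatched row widths {sorted(len(r) for r in mat)}")
        parts = header.split(None, 1)
        motif_id = parts[0]
        motif_name = parts[1].strip() if len(parts) > 1 else motif_id
        records.append(PFMRecord(motif_id=motif_id, motif_name=motif_name, counts=np.array(mat)))
        header, rows = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            continue
        m = _ROW_RE.match(line)
        if m and m.group(2).strip():
            rows.append((m.group(1), [float(x) for x in m.group(2).split()]))
            continue
        # matrix-only dialect: bare numbers
        try:
            vals = [float(x) for x in line.replace("[", " ").replace("]", " ").split()]
        except ValueError as exc:
            raise FormatError(f"unparseable PFM row: {raw!r}") from exc
        if not vals:
            raise FormatError(f"unparseable PFM row: {raw!r}")
        rows.append((None, vals))
    _flush()
    return records


def write_jaspar_pfm(records: list[PFMRecord]) -> str:
    out = []
    for rec in records:
        out.append(f">{rec.motif_id} {rec.motif_name}")
        for b, row in zip(_BASES, rec.counts):
            out.append(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_regions(text: str) -> list[PromoterRegion]:
    from Bio import SeqIO

    regions = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        strand = "-" if "strand=-" in rec.description else "+"
        regions.append(PromoterRegion(name=rec.id, sequence=str(rec.seq), strand=strand))
    return regions


def write_fasta_regions(regions: list[PromoterRegion]) -> str:
    lines = []
    for r in regions:
        lines.append(f">{r.name} strand={r.strand}")
        for i in range(0, len(r.sequence), 70):
            lines.append(r.sequence[i : i + 70])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# generic report serialisation
# ---------------------------------------------------------------------------

def write_report(rows: list[dict], format: str = "tsv") -> str:
    """Serialise homogeneous report rows to TSV or JSON with a deterministic
    column order (the first row's key order)."""
    if format not in {"tsv", "json"}:
        raise ValueError("format must be 'tsv' or 'json'")
    if not rows:
        return "" if format == "json" else "\n"
    schema = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != schema:
            raise ValidationError(f"row {i} schema {list(row.keys())} differs from {schema}")
    if format == "json":
        return json.dumps(rows, indent=2, default=float)
    df = pd.DataFrame(rows, columns=schema)
    return _to_tsv(df)


def read_report(text: str, format: str = "tsv") -> list[dict]:
    if format == "json":
        return json.loads(text)
    df = _read_tsv(text)
    return df.to_dict(orient="records")


def hits_to_bed(hits, region_names: dict | None = None) -> str:
    """BED6 lines for motif hits: chrom=region, score=−10·log10(p) capped
    at 1000, name=motif_id."""
    lines = []
    for h in hits:
        score = 1000 if h.p <= 0 else min(1000, int(round(-10 * np.log10(h.p))))
        lines.append(f"{h.region}\t{h.start}\t{h.end}\t{h.motif_id}\t{score}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
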