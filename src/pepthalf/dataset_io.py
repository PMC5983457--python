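"""Reading, curation and splitting of peptide blood-half-life datasets.

Datasets are tables of peptides (one-letter sequences and/or SMILES for
chemically modified entries) with an experimentally measured half-life in
blood, in seconds.  Half-lives are modelled throughout on a log2-seconds
scale, so a unit difference in the response corresponds to a doubling of
stability.

Curation applies the standard filters for this class of data: peptide
length within [5, 50] residues and half-life within [20 s, 24 h], followed
by removal of duplicate sequences.  Both bounds are inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard one-letter amino-acid codes, fixed vector order
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: curation bounds (inclusive)
MIN_LENGTH = 5
MAX_LENGTH = 50
MIN_HALF_LIFE_S = 20.0
MAX_HALF_LIFE_S = 86400.0  # 24 hours


class FormatError(ValueError):
    """A table or file does not match the expected layout."""


class RowError(ValueError):
    """A single input row is invalid; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide with its measured blood half-life.

    ``sequence`` may be ``None`` only when ``smiles`` is present (a fully
    modified entry carried as structure only).  ``log2_half_life`` is
    derived from ``half_life_seconds`` and kept consistent with it.
    """

    id: str
    sequence: str | None
    half_life_seconds: float
    smiles: str | None = None
    is_modified: bool = False
    log2_half_life: float = field(default=math.nan)

    def __post_init__(self):
        if self.sequence is None and self.smiles is None:
            raise ValueError(f"record {self.id!r}: needs a sequence or a SMILES")
        if not (self.half_life_seconds > 0):
            raise ValueError(
                f"record {self.id!r}: half-life must be positive, got "
                f"{self.half_life_seconds!r}"
            )
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
            if not self.is_modified:
                bad = set(self.sequence) - _ALPHABET_SET
                if bad:
                    raise ValueError(
                        f"record {self.id!r}: non-standard residue(s) "
                        f"{sorted(bad)} without a SMILES"
                    )
        expected = math.log2(self.half_life_seconds)
        if math.isnan(self.log2_half_life):
            object.__setattr__(self, "log2_half_life", expected)
        elif abs(self.log2_half_life - expected) > 1e-9:
            raise ValueError(
                f"record {self.id!r}: log2_half_life {self.log2_half_life} "
                f"inconsistent with half_life_seconds {self.half_life_seconds}"
            )

    @property
    def length(self) -> int | None:
        return None if self.sequence is None else len(self.sequence)

    def dedup_key(self) -> str:
        if self.sequence is not None:
            return "seq:" + self.sequence
        return "smi:" + (self.smiles or "")


@dataclass
class HalfLifeDataset:
    """An ordered collection of :class:`PeptideRecord`."""

    records: list[PeptideRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def log2_half_lives(self) -> np.ndarray:
        return np.array([r.log2_half_life for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "half_life_seconds": [r.half_life_seconds for r in self.records],
                "log2_half_life": [r.log2_half_life for r in self.records],
                "is_modified": [r.is_modified for r in self.records],
            }
        )

    def write_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().drop(columns="is_modified").to_csv(fh, index=False)


@dataclass
class CurationReport:
    """Per-filter removal counts produced by :func:`curate_dataset`."""

    n_input: int = 0
    removed_length: int = 0
    removed_half_life: int = 0
    removed_duplicate: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# reading


def _records_from_frame(df: pd.DataFrame, provenance: str) -> HalfLifeDataset:
    for col in ("id", "sequence", "half_life_seconds"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    has_smiles = "smiles" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw_t = getattr(row, "half_life_seconds")
        try:
            t = float(raw_t)
        except (TypeError, ValueError):
            raise RowError(i, f"non-numeric half-life {raw_t!r}") from None
        if not (t > 0) or math.isnan(t):
            raise RowError(i, f"non-positive half-life {raw_t!r}")
        seq = getattr(row, "sequence")
        seq = None if (seq is None or (isinstance(seq, float) and math.isnan(seq)) or seq == "") else str(seq)
        smi = getattr(row, "smiles", None) if has_smiles else None
        smi = None if (smi is None or (isinstance(smi, float) and math.isnan(smi)) or smi == "") else str(smi)
        is_modified = smi is not None and (
            seq is None or bool(set(seq.upper()) - _ALPHABET_SET)
        )
        try:
            records.append(
                PeptideRecord(
                    id=str(getattr(row, "id")),
                    sequence=seq,
                    smiles=smi,
                    half_life_seconds=t,
                    is_modified=is_modified,
                )
            )
        except ValueError as e:
            raise RowError(i, str(e)) from None
    return HalfLifeDataset(records, provenance=provenance)


def read_peptide_table(
    path,
    format: str = "csv",
    half_life_table=None,
) -> HalfLifeDataset:
    """Read a peptide half-life table.

    Parameters
    ----------
    path
        CSV/TSV file with header columns ``id, sequence, half_life_seconds``
        (``smiles`` optional), an ``.xlsx`` export of the same layout, or a
        FASTA file when ``format="fasta+table"``.
    format
        One of ``csv``, ``tsv``, ``fasta+table``.  With ``fasta+table`` the
        sequences come from the FASTA at ``path`` and half-lives from
        ``half_life_table``, a two-column (id, half_life_seconds) CSV.
    """
    path = str(path)
    if format == "csv":
        if path.endswith(".xlsx"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path, comment="#")
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
    elif format == "fasta+table":
        if half_life_table is None:
            raise FormatError("fasta+table format needs a half_life_table path")
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        tbl = pd.read_csv(half_life_table, comment="#")
        if "id" not in tbl.columns or "half_life_seconds" not in tbl.columns:
            raise FormatError(
                "half-life table needs columns 'id' and 'half_life_seconds'"
            )
        missing = [i for i in tbl["id"].astype(str) if i not in seqs]
        if missing:
            raise FormatError(f"ids in half-life table absent from FASTA: {missing[:5]}")
        df = pd.DataFrame(
            {
                "id": tbl["id"].astype(str),
                "sequence": [seqs[str(i)] for i in tbl["id"]],
                "half_life_seconds": tbl["half_life_seconds"],
            }
        )
    else:
        raise FormatError(f"unknown format {format!r}")
    df.columns = [str(c).strip() for c in df.columns]
    return _records_from_frame(df, provenance=path)


# ---------------------------------------------------------------------------
# curation


def curate_dataset(
    ds: HalfLifeDataset, return_report: bool = False
) -> HalfLifeDataset | tuple[HalfLifeDataset, CurationReport]:
    """Apply the standard length/half-life filters and deduplicate.

    Retains records with length in [5, 50] (records without a sequence are
    not length-filtered) and half-life in [20 s, 86400 s], inclusive; then
    keeps the first occurrence of each identical sequence (or SMILES for
    sequence-less entries).
    """
    if len(ds) == 0:
        raise ValueError("cannot curate an empty dataset")
    report = CurationReport(n_input=len(ds))
    kept: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in ds:
        if rec.length is not None and not (MIN_LENGTH <= rec.length <= MAX_LENGTH):
            report.removed_length += 1
            continue
        if not (MIN_HALF_LIFE_S <= rec.half_life_seconds <= MAX_HALF_LIFE_S):
            report.removed_half_life += 1
            continue
        key = rec.dedup_key()
        if key in seen:
            report.removed_duplicate += 1
            continue
        seen.add(key)
        kept.append(rec)
    report.n_output = len(kept)
    if not kept:
        logger.warning("curation removed every record (input n=%d)", len(ds))
    out = HalfLifeDataset(kept, provenance=ds.provenance + " [curated]")
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# splitting


def make_independent_splits(
    ds: HalfLifeDataset,
    fraction: float,
    n_repeats: int,
    seed: int,
) -> list[tuple[HalfLifeDataset, HalfLifeDataset]]:
    """Draw ``n_repeats`` random train/test partitions.

    Each repeat holds out ``round(fraction * n)`` records chosen uniformly
    without replacement; train and test are disjoint and union to the
    dataset.  Reproducible for a given ``seed``.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(ds)
    n_test = int(round(fraction * n))
    if n_test < 1:
        raise ValueError(f"fraction {fraction} leaves an empty test set at n={n}")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(int(n_repeats)):
        test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
        train = [ds[i] for i in range(n) if i not in test_idx]
        test = [ds[i] for i in range(n) if i in test_idx]
        splits.append(
            (
                HalfLifeDataset(train, provenance=ds.provenance + " [train]"),
                HalfLifeDataset(test, provenance=ds.provenance + " [test]"),
            )
        )
    return splits
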