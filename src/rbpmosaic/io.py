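"""Dataset I/O: amino-acid/nucleotide FASTA plus a tab-separated metadata table.

The metadata TSV is UTF-8, one header row, '.' for missing values.  FASTA
ids must match the ``rbp_id`` column exactly.  ``read_dataset`` and
``write_dataset`` round-trip records field-for-field.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import RBPRecord, RecordError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MISSING = "."

METADATA_COLUMNS = [
    "rbp_id",
    "phage_id",
    "genus",
    "lifestyle",
    "source",
    "rbp_index",
    "evidence_group",
    "host_strain",
    "host_serogroup",
    "serogroup_evidence",
    "prophage_score",
    "curated_anchor_end",
    "split_rbp",
]


class DatasetError(ValueError):
    """Raised for malformed dataset files."""


def _read_fasta(path: PathLike) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DatasetError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_metadata(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        na_values=[MISSING],
        keep_default_na=False,
        encoding="utf-8",
    )
    if "rbp_id" not in df.columns:
        raise DatasetError(f"metadata {path} lacks an rbp_id column")
    dupes = df["rbp_id"][df["rbp_id"].duplicated()]
    if not dupes.empty:
        raise DatasetError(
            f"duplicate rbp_id in metadata {path}: {sorted(set(dupes))}"
        )
    return df


def _row_to_kwargs(row: pd.Series) -> dict:
    def get(col: str) -> Optional[str]:
        val = row.get(col)
        if val is None or pd.isna(val):
            return None
        return str(val)

    kwargs: dict = {}
    for col in ("phage_id", "genus", "lifestyle", "source", "evidence_group",
                "host_strain", "host_serogroup", "serogroup_evidence"):
        val = get(col)
        if val is not None:
            kwargs[col] = val
    if get("rbp_index") is not None:
        kwargs["rbp_index"] = int(float(get("rbp_index")))
    if get("prophage_score") is not None:
        kwargs["prophage_score"] = float(get("prophage_score"))
    if get("curated_anchor_end") is not None:
        kwargs["curated_anchor_end"] = int(float(get("curated_anchor_end")))
    if get("split_rbp") is not None:
        kwargs["split_rbp"] = get("split_rbp").lower() in ("true", "1", "yes")
    kwargs.setdefault("phage_id", "unknown")
    kwargs.setdefault("genus", "unknown")
    return kwargs


def read_dataset(
    fasta_path: PathLike,
    metadata_path: PathLike,
    nt_fasta_path: Optional[PathLike] = None,
) -> List[RBPRecord]:
    """Read one RBPRecord per FASTA entry, in FASTA file order.

    A metadata row without a sequence is a hard error; a sequence without
    a metadata row is kept with all-unknown metadata and logged as a
    warning.
    """
    aa = _read_fasta(fasta_path)
    nt = _read_fasta(nt_fasta_path) if nt_fasta_path is not None else {}
    meta = read_metadata(metadata_path).set_index("rbp_id", drop=False)

    missing_seq = [rid for rid in meta.index if rid not in aa]
    if missing_seq:
        raise DatasetError(
            f"metadata rows without a FASTA sequence: {sorted(missing_seq)}"
        )

    records: List[RBPRecord] = []
    for rbp_id, seq in aa.items():
        if rbp_id in meta.index:
            kwargs = _row_to_kwargs(meta.loc[rbp_id])
        else:
            logger.warning(
                "sequence %s has no metadata row; using unknown metadata", rbp_id
            )
            kwargs = {"phage_id": "unknown", "genus": "unknown"}
        try:
            records.append(
                RBPRecord(
                    rbp_id=rbp_id,
                    aa_sequence=seq,
                    nt_sequence=nt.get(rbp_id),
                    **kwargs,
                )
            )
        except RecordError as exc:
            raise DatasetError(str(exc)) from exc
    return records


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def metadata_frame(records: Sequence[RBPRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "rbp_id": r.rbp_id,
                "phage_id": r.phage_id,
                "genus": r.genus,
                "lifestyle": r.lifestyle.value,
                "source": r.source.value,
                "rbp_index": str(r.rbp_index),
                "evidence_group": r.evidence_group.value,
                "host_strain": _fmt(r.host_strain),
                "host_serogroup": _fmt(r.host_serogroup),
                "serogroup_evidence": r.serogroup_evidence.value,
                "prophage_score": _fmt(r.prophage_score),
                "curated_anchor_end": _fmt(r.curated_anchor_end),
                "split_rbp": _fmt(r.split_rbp),
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_dataset(
    records: Sequence[RBPRecord],
    fasta_path: PathLike,
    metadata_path: PathLike,
    nt_fasta_path: Optional[PathLike] = None,
) -> None:
    """Write aa FASTA + metadata TSV (+ nt FASTA for records carrying DNA)."""
    SeqIO.write(
        (SeqRecord(Seq(r.aa_sequence), id=r.rbp_id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    metadata_frame(records).to_csv(
        metadata_path, sep="\t", index=False, encoding="utf-8"
    )
    if nt_fasta_path is not None:
        SeqIO.write(
            (
                SeqRecord(Seq(r.nt_sequence), id=r.rbp_id, description="")
                for r in records
                if r.nt_sequence is not None
            ),
            str(nt_fasta_path),
            "fasta",
        )
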