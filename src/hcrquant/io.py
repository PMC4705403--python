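"""Readers and writers for the package's plain-text contract formats.

Plate tables are long-format CSV (well, amplicon, cycle, fluorescence); flow event
tables are CSV (event, RFP, GFP, APC); reads are 4-line FASTQ with Phred+33
constant quality; references are FASTA. Ground truth for simulated datasets is
written as JSON beside the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qpcr import AmplificationCurve, PlateQuant

PLATE_COLUMNS = ["well", "amplicon", "cycle", "fluorescence"]
FLOW_COLUMNS = ["event", "RFP", "GFP", "APC"]


def write_plate_csv(curves: list[AmplificationCurve], path) -> None:
    rows = [
        {"well": c.well_id, "amplicon": c.amplicon, "cycle": int(cy), "fluorescence": f}
        for c in curves
        for cy, f in zip(c.cycles, c.fluorescence)
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path) -> list[AmplificationCurve]:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate CSV lacks columns {missing}")
    curves = []
    for (well, amplicon), grp in df.groupby(["well", "amplicon"], sort=True):
        grp = grp.sort_values("cycle")
        curves.append(AmplificationCurve(
            well_id=str(well), amplicon=str(amplicon),
            cycles=grp["cycle"].to_numpy(), fluorescence=grp["fluorescence"].to_numpy(),
        ))
    return curves


def write_plate_quant(quant: PlateQuant, csv_path, json_path=None) -> None:
    quant.table.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "amplicon_efficiency": quant.amplicon_efficiency,
            "n_wells": int(len(quant.table)),
            "excluded": [{"well": w, "reason": r} for w, r in quant.excluded],
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))


def write_flow_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_flow_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("RFP", "GFP") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: flow CSV lacks channels {missing}")
    if "event" not in df.columns:
        df.insert(0, "event", np.arange(len(df)))
    return df


def read_spillover_csv(path):
    """Spillover matrix CSV with channel names as header and index."""
    from .flow import SpilloverMatrix

    df = pd.read_csv(path, index_col=0)
    channels = tuple(df.columns)
    if tuple(df.index) != channels:
        raise ValueError(f"{path}: spillover rows and columns must list the same channels")
    return SpilloverMatrix(df.to_numpy(dtype=float), channels)


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 40) -> None:
    """Write (id, sequence) pairs as FASTQ with a constant Phred+33 quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    with open(path) as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fastq")]


def write_fasta(name: str, sequence: str, path) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_reference_fasta(path, lesion_opposite_pos: int):
    from .variants import ReferenceTranscript

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one reference sequence, got {len(records)}")
    return ReferenceTranscript(sequence=str(records[0].seq),
                               lesion_opposite_pos=lesion_opposite_pos)


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
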