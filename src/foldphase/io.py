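"""Shared readers and writers for the pipeline's text formats.

FASTA goes through biopython; multi-model PDB through biotite; xyz
trajectories (one model per frame, one line per residue bead) through a
small reader, since the coarse bead-per-residue chains carry no atomic
topology.  Tables are CSV/TSV with explicit headers; abundance tables use
a two-row header (group, replicate).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._scales import AMINO_ACIDS
from .synthetic import ConformEnsemble

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ensemble",
    "write_ensemble",
    "read_pixel_table",
    "write_pixel_table",
    "read_abundance_table",
    "write_abundance_table",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences, preserving order; normalises to uppercase.

    Rejects duplicate ids and non-standard residues (with positions).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = [(i, a) for i, a in enumerate(seq) if a not in AMINO_ACIDS]
        if bad:
            pos = ", ".join(f"{a} at {i}" for i, a in bad[:5])
            raise ValueError(f"{rec.id}: non-standard residues ({pos})")
        seqs[rec.id] = seq
    if not seqs:
        warnings.warn(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_ensemble(path: str | Path, fmt: str | None = None) -> ConformEnsemble:
    """Read a conformational ensemble from multi-model PDB or xyz.

    All models must have the same residue count; units are Angstrom.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported ensemble format {fmt!r}")


def _read_xyz(path: Path) -> ConformEnsemble:
    """xyz trajectory: repeated blocks of (n, comment, n lines of 'AA x y z')."""
    lines = path.read_text().splitlines()
    frames, seqs = [], []
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        model += 1
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise ValueError(f"model {model}: expected {n} coordinate lines")
        seq, coords = [], []
        for ln in block:
            parts = ln.split()
            seq.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(np.array(coords))
        seqs.append("".join(seq))
        i += 2 + n
    if not frames:
        raise ValueError(f"no models in {path}")
    n0 = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n0:
            raise ValueError(f"model {k + 1} has {len(f)} residues, expected {n0}")
    return ConformEnsemble(seqs[0], np.stack(frames))


def _read_pdb(path: Path) -> ConformEnsemble:
    """One representative point per residue: the side-chain heavy-atom
    centroid when side-chain atoms are present, else the CA position."""
    import numpy as _np
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    from biotite.sequence import ProteinSequence

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack: models x atoms
    first = stack[0]
    backbone = {"N", "CA", "C", "O", "OXT"}
    res_ids = _np.unique(first.res_id)
    seq_letters, reps = [], []
    for rid in res_ids:
        in_res = first.res_id == rid
        res_name = first.res_name[in_res][0]
        seq_letters.append(ProteinSequence.convert_letter_3to1(res_name))
        side = in_res & ~_np.isin(first.atom_name, list(backbone)) & (
            first.element != "H")
        if side.any():
            reps.append(stack.coord[:, side, :].mean(axis=1))
        else:  # glycine or CA-only model
            ca = in_res & (first.atom_name == "CA")
            reps.append(stack.coord[:, ca, :].mean(axis=1))
    coords = _np.stack(reps, axis=1)  # models x residues x 3
    return ConformEnsemble("".join(seq_letters), coords)


def write_ensemble(ensemble: ConformEnsemble, path: str | Path) -> None:
    """Write an ensemble as an xyz trajectory (one bead per residue)."""
    path = Path(path)
    n = len(ensemble.sequence)
    with path.open("w") as fh:
        for k, conf in enumerate(ensemble.conformations):
            fh.write(f"{n}\nmodel {k + 1} {ensemble.label}\n")
            for aa, (x, y, z) in zip(ensemble.sequence, conf):
                fh.write(f"{aa} {x:.4f} {y:.4f} {z:.4f}\n")


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "pixel_id", "intensity_before", "intensity_after"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pixel table missing columns: {sorted(missing)}")
    return df


def write_pixel_table(pixels: pd.DataFrame, path: str | Path) -> None:
    pixels.to_csv(path, index=False)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """TSV with a two-row header (group, replicate), proteins as rows."""
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(g, int(r)) for g, r in df.columns], names=["group", "replicate"]
    )
    return df


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialise {type(x)}")
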