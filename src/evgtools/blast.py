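"""Thin subprocess wrappers around the NCBI BLAST+ binaries.

The pipeline's local alignments (translated, nucleotide and protein modes)
are produced by tblastx, blastn and blastp with tabular (outfmt 6) output,
parsed into :class:`~evgtools.similarity.HSP` records. All runs are
single-threaded for reproducibility.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

_PROGRAMS = {"translated": "tblastx", "nucleotide": "blastn", "protein": "blastp"}
_DBTYPE = {"translated": "nucl", "nucleotide": "nucl", "protein": "prot"}


def available() -> bool:
    return all(shutil.which(p) for p in ("makeblastdb", "tblastx", "blastn", "blastp"))


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def run_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    mode: str = "translated",
    evalue: float = 1e-3,
    extra_args: tuple[str, ...] = (),
) -> list:
    """All queries against a database of all subjects; returns HSP records."""
    from .similarity import parse_tabular_line

    if mode not in _PROGRAMS:
        raise ValueError(f"unknown mode {mode!r}")
    if not queries or not subjects:
        return []
    with tempfile.TemporaryDirectory(prefix="evg_blast_") as td:
        tdp = Path(td)
        qfa, sfa, db = tdp / "q.fa", tdp / "s.fa", tdp / "db"
        _write_fasta(queries, qfa)
        _write_fasta(subjects, sfa)
        subprocess.run(
            ["makeblastdb", "-in", str(sfa), "-dbtype", _DBTYPE[mode], "-out", str(db)],
            check=True, capture_output=True,
        )
        cmd = [
            _PROGRAMS[mode], "-query", str(qfa), "-db", str(db),
            "-outfmt", "6", "-evalue", str(evalue), "-num_threads", "1",
        ] + list(extra_args)
        proc = subprocess.run(cmd, check=True, capture_output=True, text=True)
    return [parse_tabular_line(line) for line in proc.stdout.splitlines() if line.strip()]
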