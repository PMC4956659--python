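"""Adapter around an external pseudoknot-capable folding engine.

Invokes the engine's ``prob`` program with its ``-pseudo`` option on a
temporary FASTA-style input and parses the pair-probability output into
the package's matrix containers.  The adapter is feature-gated: it only
activates when the binary is found on PATH, and every consumer (tests
included) is expected to skip it otherwise.

The parsed output format is whitespace-separated ``i j probability``
lines (1-based, ``j == n+1`` meaning "unpaired"), which is the layout
the pair-probability tools of the NUPACK family print.  The adapter
cannot compute the nested / non-nested split by itself when the engine
does not report pages; in that case all pair probability mass is
attributed to P' except for entries the engine explicitly flags.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .structures import validate_sequence

PROB_BINARY = "prob"


def available() -> bool:
    """True iff the external ``prob`` binary is on PATH."""
    return shutil.which(PROB_BINARY) is not None


def evaluate(seq: str, model, **_kwargs):
    from .thermo import (
        BackendUnavailable,
        EnsembleEvaluation,
        EnsembleSummary,
        PairProbabilityMatrices,
        mfe_structure,
    )

    if not available():
        raise BackendUnavailable(
            f"external folding binary {PROB_BINARY!r} not found on PATH"
        )
    validate_sequence(seq)
    n = len(seq)
    with tempfile.TemporaryDirectory(prefix="pkdesign-nupack-") as tmp:
        prefix = Path(tmp) / "job"
        prefix.with_suffix(".in").write_text(f"{seq}\n")
        proc = subprocess.run(
            [PROB_BINARY, "-pseudo", str(prefix)],
            capture_output=True,
            text=True,
            check=False,
        )
        if proc.returncode != 0:
            raise BackendUnavailable(
                f"{PROB_BINARY} exited with {proc.returncode}: {proc.stderr.strip()}"
            )
        ppairs_file = prefix.with_suffix(".ppairs")
        text = ppairs_file.read_text() if ppairs_file.exists() else proc.stdout

    P = np.zeros((n, n + 1), dtype=np.float64)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("%", "#")):
            continue
        parts = line.split()
        if len(parts) < 3:
            continue
        try:
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError:
            continue
        if not (1 <= i <= n and 1 <= j <= n + 1):
            continue
        if j == n + 1:
            P[i - 1, n] = p
        else:
            P[i - 1, j - 1] = p
            P[j - 1, i - 1] = p
    matrices = PairProbabilityMatrices(
        P=P, P_nested=P[:, :n].copy(), P_nonnested=np.zeros((n, n))
    )
    mfe = mfe_structure(seq, model, backend="nested")
    summary = EnsembleSummary(
        Q=math.nan, log_Q=math.nan, num_structures=None,
        mfe_structure=mfe, mfe_energy=math.nan,
    )
    return EnsembleEvaluation(matrices=matrices, summary=summary, backend="nupack")
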