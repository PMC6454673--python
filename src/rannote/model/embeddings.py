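"""Plain-text word-vector file I/O (word2vec text dialect).

First line is ``<count> <dim>``; each following line is
``symbol v1 ... vdim`` separated by single spaces.  Symbols missing from the
file keep their uniform random initialization when applied to a table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_embedding_file(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Return ``(vectors, dim)`` from a word2vec-style text file."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError("empty embedding file")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError(f"bad header {lines[0]!r}; expected '<count> <dim>'")
    count, dim = int(head[0]), int(head[1])
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise ValueError(
                f"line {lineno}: expected symbol + {dim} values, got "
                f"{len(parts) - 1}"
            )
        vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    if len(vectors) != count:
        raise ValueError(
            f"header declares {count} vectors but file contains {len(vectors)}"
        )
    return vectors, dim


def write_embedding_file(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    if not vectors:
        raise ValueError("refusing to write an empty embedding file")
    dim = len(next(iter(vectors.values())))
    lines = [f"{len(vectors)} {dim}"]
    for symbol, vec in vectors.items():
        lines.append(symbol + " " + " ".join(f"{v:.6f}" for v in vec))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
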