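"""Kangxi-radical lookup and radical embeddings.

The radical (部首) is the head graphical component of a Chinese character;
the 214 canonical Kangxi radicals act as coarse semantic classes — e.g. the
sickness radical 疒 (104) groups 痛/疹/症/病, the water radical 水/氵 (85)
groups 液/注/滴.  Characters sharing a radical often share a semantic field,
which is the signal the tagger exploits: each character contributes, besides
its token vector, a trainable embedding of its radical identifier.

Radical identity here is the canonical Kangxi *number* (1-214), not the
glyph, so variant surface forms (氵 for 水, 忄 for 心, ...) collapse onto
one identifier.  Identifier 0 is the "no radical" sentinel used for
non-CJK characters (Latin letters, digits, punctuation) and for the
[CLS]/[SEP]/[PAD] control tokens.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np

N_RADICALS = 214  # canonical Kangxi radicals; identifiers 1..214, 0 = none
DEFAULT_TABLE_RESOURCE = "kangxi_radicals.tsv"

logger = logging.getLogger(__name__)

_CJK_RANGES = (
    (0x4E00, 0x9FFF),    # CJK Unified Ideographs
    (0x3400, 0x4DBF),    # Extension A
    (0x2E80, 0x2EFF),    # CJK Radicals Supplement
    (0x2F00, 0x2FDF),    # Kangxi Radicals block
    (0xF900, 0xFAFF),    # Compatibility Ideographs
)


def is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _CJK_RANGES)


class RadicalIndex:
    """Total map character -> Kangxi radical identifier (0-214).

    Unmapped CJK characters return the 0 sentinel and are logged once each;
    non-CJK characters return 0 silently.
    """

    def __init__(self, table: dict[str, int]):
        for ch, rid in table.items():
            if not (1 <= rid <= N_RADICALS):
                raise ValueError(
                    f"radical id {rid} for {ch!r} outside 1..{N_RADICALS}"
                )
        self._table = dict(table)
        self._warned: set[str] = set()

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, ch: str) -> bool:
        return ch in self._table

    def lookup(self, ch: str) -> int:
        if len(ch) != 1:  # control tokens such as [CLS]
            return 0
        rid = self._table.get(ch)
        if rid is not None:
            return rid
        if is_cjk(ch) and ch not in self._warned:
            self._warned.add(ch)
            logger.info("character %r has no radical entry; using sentinel 0", ch)
        return 0


def radical_of(ch: str, index: RadicalIndex) -> int:
    """Canonical Kangxi radical identifier of a single character (0 if none)."""
    if len(ch) != 1:
        raise ValueError("radical_of expects a single character")
    return index.lookup(ch)


def build_radical_index(table_file: str | Path | None = None) -> RadicalIndex:
    """Load a character->radical table (UTF-8 TSV: character, kangxi_index).

    With no argument, loads the packaged table covering the 214 radical
    glyphs, common variant forms, and the characters of the bundled
    clinical vocabulary.  Malformed rows are rejected with their row number.
    """
    if table_file is None:
        text = (
            resources.files("radner").joinpath("data", DEFAULT_TABLE_RESOURCE)
        ).read_text(encoding="utf-8")
    else:
        text = Path(table_file).read_text(encoding="utf-8")
    table: dict[str, int] = {}
    for row_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or len(parts[0]) != 1:
            raise ValueError(f"radical table row {row_no}: malformed line {line!r}")
        ch, rid_s = parts
        try:
            rid = int(rid_s)
        except ValueError:
            raise ValueError(
                f"radical table row {row_no}: non-integer radical id {rid_s!r}"
            ) from None
        if not (1 <= rid <= N_RADICALS):
            raise ValueError(
                f"radical table row {row_no}: radical id {rid} outside 1..{N_RADICALS}"
            )
        table[ch] = rid
    return RadicalIndex(table)


class RadicalEmbeddingTable:
    """Trainable embedding row per radical identifier 0..214.

    Rows are initialized uniformly on [-0.5/dim, +0.5/dim] from ``seed`` and
    updated during tagger training (the 0 row serves every radical-less
    position).
    """

    def __init__(self, dim: int = 20, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        scale = 0.5 / dim
        self.vectors = rng.uniform(-scale, scale, size=(N_RADICALS + 1, dim))

    def __getitem__(self, rid: int) -> np.ndarray:
        return self.vectors[rid]


def embed_radicals(
    chars: "list[str] | tuple[str, ...] | str",
    index: RadicalIndex,
    table: RadicalEmbeddingTable,
) -> np.ndarray:
    """Radical embedding vectors for a character sequence, shape (n, dim)."""
    ids = [index.lookup(ch) for ch in chars]
    if not ids:
        return np.zeros((0, table.dim))
    return table.vectors[np.asarray(ids, dtype=np.intp)]
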