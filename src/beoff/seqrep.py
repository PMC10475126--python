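"""Pairing, alignment, encoding and classification of gRNA/off-target sequences.

A guide--target pair is treated as a single object: the 20-nt protospacer plus
3-nt PAM on the guide side, and the candidate off-target DNA on the other.
Gapped global alignment introduces a ``-`` token for DNA bulges (extra base in
the target, i.e. a gap in the guide) and RNA bulges (a base of the guide with
no partner, i.e. a gap in the target). Aligned strings are mapped to integer
sequences over the fixed vocabulary

    {<pad>: 0, A: 1, C: 2, G: 3, T: 4, -: 5}

with right padding to a common batch length, which is the input representation
consumed by the regression model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAD, GAP = "<pad>", "-"
VOCAB: dict[str, int] = {PAD: 0, "A": 1, "C": 2, "G": 3, "T": 4, GAP: 5}
_INDEX_TO_TOKEN = {i: t for t, i in VOCAB.items()}

PROTOSPACER_LEN = 20
PAM_LEN = 3

#: the fixed mutation-type taxonomy of the screen library
MUTATION_TYPES = (
    "on",
    "1mis", "2mis", "3mis", "4mis", "5mis", "6mis",
    "1ins", "2ins",
    "1del", "2del",
    "mix",
    "nontarget",
)
#: label for alignments whose event counts fall outside the taxonomy
OUT_OF_TAXONOMY = "other"

_DNA = set("ACGT")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


def _check_dna(seq: str, name: str) -> None:
    if not seq:
        raise InvalidSequenceError(f"{name} is empty")
    bad = set(seq) - _DNA
    if bad:
        raise InvalidSequenceError(f"{name} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentScoring:
    """End-to-end alignment scoring.

    The defaults (match +1, mismatch 0, gap -0.5) make every printed library
    alignment score-optimal while keeping gap placement deterministic through
    the fixed traceback preference substitution > gap-in-off > gap-in-guide.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -0.5


def align_pair(
    guide_plus_pam: str,
    offtarget: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[str, str]:
    """Global (Needleman-Wunsch) alignment of a guide(+PAM) to a candidate.

    Returns one optimal alignment ``(aligned_guide, aligned_off)`` selected
    deterministically: the traceback walks from the end of the alignment and,
    among score-equivalent moves, prefers a substitution column, then a gap in
    the off-target, then a gap in the guide.
    """
    _check_dna(guide_plus_pam, "guide")
    _check_dna(offtarget, "offtarget")
    g, o = guide_plus_pam, offtarget
    n, m = len(g), len(o)
    sc = scoring
    S = np.empty((n + 1, m + 1))
    S[:, 0] = np.arange(n + 1) * sc.gap
    S[0, :] = np.arange(m + 1) * sc.gap
    for i in range(1, n + 1):
        gi = g[i - 1]
        row, prev = S[i], S[i - 1]
        for j in range(1, m + 1):
            d = prev[j - 1] + (sc.match if gi == o[j - 1] else sc.mismatch)
            u = prev[j] + sc.gap
            lft = row[j - 1] + sc.gap
            row[j] = max(d, u, lft)
    ag: list[str] = []
    ao: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = S[i, j]
        if (
            i > 0
            and j > 0
            and np.isclose(here, S[i - 1, j - 1] + (sc.match if g[i - 1] == o[j - 1] else sc.mismatch))
        ):
            ag.append(g[i - 1]); ao.append(o[j - 1]); i -= 1; j -= 1
        elif i > 0 and np.isclose(here, S[i - 1, j] + sc.gap):
            ag.append(g[i - 1]); ao.append(GAP); i -= 1
        else:
            ag.append(GAP); ao.append(o[j - 1]); j -= 1
    return "".join(reversed(ag)), "".join(reversed(ao))


def encode_sequence(aligned: str, pad_to: int | None = None) -> np.ndarray:
    """Map an aligned (possibly gapped) sequence to its integer encoding.

    Right-pads with the ``<pad>`` index 0 up to ``pad_to`` when given.
    """
    try:
        idx = [VOCAB[c] for c in aligned]
    except KeyError as exc:
        raise InvalidSequenceError(f"unknown character {exc.args[0]!r} in aligned sequence") from None
    if pad_to is not None:
        if len(idx) > pad_to:
            raise ValueError(f"sequence length {len(idx)} exceeds pad_to={pad_to}")
        idx.extend([VOCAB[PAD]] * (pad_to - len(idx)))
    return np.asarray(idx, dtype=np.int64)


def decode_sequence(encoded: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; strips trailing padding."""
    out = []
    for v in np.asarray(encoded).tolist():
        if v == VOCAB[PAD]:
            break
        out.append(_INDEX_TO_TOKEN[v])
    return "".join(out)


def _protospacer_columns(aligned_guide: str, pam_len: int = PAM_LEN) -> int:
    """Number of leading alignment columns covering the protospacer.

    The PAM is the trailing ``pam_len`` non-gap guide characters; columns from
    the first of those onward are excluded from mutation counting.
    """
    seen = 0
    for col in range(len(aligned_guide) - 1, -1, -1):
        if aligned_guide[col] != GAP:
            seen += 1
            if seen == pam_len:
                return col
    raise ValueError("aligned guide shorter than the PAM")


def count_mutation_events(
    aligned_guide: str, aligned_off: str, pam_len: int = PAM_LEN
) -> tuple[int, int, int]:
    """Count (mismatches, deletions, insertions) over the protospacer region.

    A gap in the off-target is a deletion (RNA bulge); a gap in the guide is an
    insertion into the target (DNA bulge). PAM columns are not counted.
    """
    if len(aligned_guide) != len(aligned_off):
        raise ValueError("aligned strings must have equal length")
    stop = _protospacer_columns(aligned_guide, pam_len)
    mis = dele = ins = 0
    for a, b in zip(aligned_guide[:stop], aligned_off[:stop]):
        if a == GAP and b == GAP:
            raise ValueError("column with gaps on both sides")
        if a == GAP:
            ins += 1
        elif b == GAP:
            dele += 1
        elif a != b:
            mis += 1
    return mis, dele, ins


def classify_mutation_type(
    aligned_guide: str, aligned_off: str, pam_len: int = PAM_LEN
) -> str:
    """Assign the library taxonomy label from the aligned protospacer events.

    on = identical; ``k``mis = k substitutions only (k = 1..6); ``k``ins /
    ``k``del = k target insertions / deletions only (k = 1..2); mix =
    substitutions combined with indels. Event profiles outside the taxonomy
    return :data:`OUT_OF_TAXONOMY`.
    """
    m, d, i = count_mutation_events(aligned_guide, aligned_off, pam_len)
    if m == d == i == 0:
        return "on"
    if d == i == 0:
        return f"{m}mis" if 1 <= m <= 6 else OUT_OF_TAXONOMY
    if m == 0 and i == 0:
        return f"{d}del" if d <= 2 else OUT_OF_TAXONOMY
    if m == 0 and d == 0:
        return f"{i}ins" if i <= 2 else OUT_OF_TAXONOMY
    if m >= 1 and d + i >= 1:
        return "mix"
    return OUT_OF_TAXONOMY


@dataclass
class GuideTargetPair:
    """One gRNA(+PAM) / off-target pair with its alignment and group label."""

    group_id: str
    guide_seq: str
    offtarget_seq: str
    aligned_guide: str
    aligned_off: str
    mutation_type: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.aligned_guide) != len(self.aligned_off):
            raise ValueError("aligned strings must have equal length")
        if self.aligned_guide.replace(GAP, "") != self.guide_seq:
            raise ValueError("aligned_guide does not reduce to guide_seq")
        if self.aligned_off.replace(GAP, "") != self.offtarget_seq:
            raise ValueError("aligned_off does not reduce to offtarget_seq")
        if not self.mutation_type:
            self.mutation_type = classify_mutation_type(self.aligned_guide, self.aligned_off)

    @classmethod
    def from_sequences(
        cls,
        group_id: str,
        guide_plus_pam: str,
        offtarget: str,
        scoring: AlignmentScoring = AlignmentScoring(),
    ) -> "GuideTargetPair":
        ag, ao = align_pair(guide_plus_pam, offtarget, scoring)
        return cls(group_id, guide_plus_pam, offtarget, ag, ao)

    @property
    def length(self) -> int:
        return len(self.aligned_guide)

    def encode(self, pad_to: int | None = None) -> "EncodedPair":
        T = pad_to if pad_to is not None else self.length
        return EncodedPair(
            x1=encode_sequence(self.aligned_guide, T),
            x2=encode_sequence(self.aligned_off, T),
            true_length=self.length,
        )


@dataclass(frozen=True)
class EncodedPair:
    """Equal-length integer encodings of an aligned pair, right-padded."""

    x1: np.ndarray
    x2: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        if self.x1.shape != self.x2.shape:
            raise ValueError("x1 and x2 must have identical shape")
        if self.true_length > self.x1.shape[-1]:
            raise ValueError("true_length exceeds padded length")


def encode_pairs(pairs: list[GuideTargetPair], pad_to: int | None = None):
    """Batch-encode pairs to two (n, T) integer arrays plus true lengths."""
    if not pairs:
        raise ValueError("empty pair list")
    T = pad_to if pad_to is not None else max(p.length for p in pairs)
    x1 = np.stack([encode_sequence(p.aligned_guide, T) for p in pairs])
    x2 = np.stack([encode_sequence(p.aligned_off, T) for p in pairs])
    lengths = np.array([p.length for p in pairs], dtype=np.int64)
    return x1, x2, lengths


# ---------------------------------------------------------------------------
# tabular interfaces

PAIR_TABLE_COLUMNS = [
    "group_id", "guide_seq", "offtarget_seq", "aligned_guide", "aligned_off", "mutation_type",
]


def pairs_to_frame(pairs: list[GuideTargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.group_id, p.guide_seq, p.offtarget_seq, p.aligned_guide, p.aligned_off, p.mutation_type)
            for p in pairs
        ],
        columns=PAIR_TABLE_COLUMNS,
    )


def frame_to_pairs(df: pd.DataFrame) -> list[GuideTargetPair]:
    pairs = []
    for row in df.itertuples(index=False):
        if hasattr(row, "aligned_guide") and isinstance(row.aligned_guide, str) and row.aligned_guide:
            pairs.append(
                GuideTargetPair(
                    str(row.group_id), row.guide_seq, row.offtarget_seq,
                    row.aligned_guide, row.aligned_off,
                    getattr(row, "mutation_type", "") or "",
                )
            )
        else:
            pairs.append(GuideTargetPair.from_sequences(str(row.group_id), row.guide_seq, row.offtarget_seq))
    return pairs


def read_pair_table(path) -> list[GuideTargetPair]:
    """Read a TSV pair table; designed aligned strings are used when present."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"group_id", "guide_seq", "offtarget_seq"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table is missing columns: {sorted(missing)}")
    if "aligned_guide" not in df.columns:
        df["aligned_guide"] = ""
        df["aligned_off"] = ""
    return frame_to_pairs(df)


def read_casoffinder(path) -> list[GuideTargetPair]:
    """Read Cas-OFFinder output into guide/off-target pairs.

    Accepts the classic 6-column dialect (pattern, chromosome, position,
    candidate, strand, mismatches) and the bulge-annotated dialect whose first
    column is the bulge type (X / DNA / RNA) followed by crRNA and DNA columns
    that already carry ``-`` gap characters. The pattern's ``N`` positions
    (degenerate PAM) are resolved from the candidate sequence.
    """
    pairs: list[GuideTargetPair] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] in {"X", "DNA", "RNA"}:
                crrna, dna = f[1].upper(), f[2].upper()
                chrom, pos = f[3], f[4]
            else:
                crrna, dna = f[0].upper(), f[3].upper()
                chrom, pos = f[1], f[2]
            # resolve degenerate pattern positions from the candidate
            ag = "".join(d if c == "N" and d != GAP else c for c, d in zip(crrna, dna))
            ao = dna
            guide = ag.replace(GAP, "")
            off = ao.replace(GAP, "")
            pairs.append(
                GuideTargetPair(
                    group_id=guide, guide_seq=guide, offtarget_seq=off,
                    aligned_guide=ag, aligned_off=ao,
                )
            )
    return pairs
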