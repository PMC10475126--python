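"""Quantification of pooled gRNA-target screens: FASTQ -> editing efficiencies.

Each library oligo couples a gRNA with its designed (possibly mutated) target
on one molecule, so a single amplicon read carries both the guide identity and
the editing outcome. The fixed oligo layout is::

    left flank (20) | gRNA (20) | BsmBI (11) | barcode1 (20) | BsmBI (11) |
    barcode2 (15) | GTACT | protospacer+PAM-N (variable) | GG | right flank (18)

Processing follows the screen's quantification rules: bases under Q10 are
masked to ``N``; a read is valid only when both designed barcodes identify a
unique oligo; a read counts as edited when at least one editable base (A for
ABE, C for CBE) shows the canonical conversion relative to the designed
target; per-pair efficiency is edited / valid reads, with pairs under the
minimum read count dropped; replicate efficiencies are averaged and the
off:on-target ratio normalises each off-target by its group's on-target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

LEFT_FLANK = "TGTGGAAAGGACGAAACACC"
BSMBI_1 = "GTTTTGAGACG"
BSMBI_2 = "CGTCTCGCTCC"
RIGHT_FLANK = "CTTGGCGTAACTAGATCT"
TARGET_PREFIX = "GTACT"
TARGET_SUFFIX = "GG"
GRNA_LEN = 20
BARCODE1_LEN = 20
BARCODE2_LEN = 15

QUALITY_MASK_THRESHOLD = 10
MIN_VALID_READS = 100

_CONVERSION = {"ABE": ("A", "G"), "CBE": ("C", "T")}

DESIGN_COLUMNS = [
    "oligo_id", "group_id", "grna", "barcode1", "barcode2",
    "target", "offtarget_seq", "aligned_guide", "aligned_off", "mutation_type",
]


@dataclass
class LibraryDesign:
    """The designed oligo library.

    ``table`` must carry :data:`DESIGN_COLUMNS`; ``target`` is the variable
    target segment (off-target protospacer plus the degenerate PAM base,
    without the GTACT/GG anchors).
    """

    table: pd.DataFrame
    _barcode_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table is missing columns: {sorted(missing)}")
        dup = self.table.duplicated(subset=["barcode1", "barcode2"])
        if dup.any():
            raise ValueError("barcode pairs are not unique per oligo")
        self._barcode_index = {
            (r.barcode1, r.barcode2): r.oligo_id for r in self.table.itertuples()
        }
        self.table = self.table.set_index("oligo_id", drop=False)

    def lookup(self, barcode1: str, barcode2: str):
        return self._barcode_index.get((barcode1, barcode2))

    def oligo(self, oligo_id):
        return self.table.loc[oligo_id]

    def build_oligo_sequence(self, oligo_id) -> str:
        """Assemble the full oligonucleotide for one design row."""
        r = self.oligo(oligo_id)
        return (
            LEFT_FLANK + r.grna + BSMBI_1 + r.barcode1 + BSMBI_2 + r.barcode2
            + TARGET_PREFIX + r.target + TARGET_SUFFIX + RIGHT_FLANK
        )

    @classmethod
    def from_tsv(cls, path) -> "LibraryDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mask_low_quality(read: str, quals, threshold: int = QUALITY_MASK_THRESHOLD) -> str:
    """Mask bases whose Phred score is below ``threshold`` with ``N``.

    ``quals`` is a sequence of integer scores or a Sanger-encoded string.
    """
    if isinstance(quals, str):
        quals = [ord(c) - 33 for c in quals]
    if len(quals) != len(read):
        raise ValueError("read and quality lengths differ")
    return "".join("N" if q < threshold else b for b, q in zip(read, quals))


@dataclass(frozen=True)
class ParsedRead:
    oligo_id: object
    grna_region: str
    target_region: str


def parse_and_validate(read: str, design: LibraryDesign):
    """Segment a masked read by the oligo layout and identify its oligo.

    Returns ``(ParsedRead, None)`` on success or ``(None, reason)`` where the
    reason codes are ``too_short``, ``barcode`` (no unique designed barcode
    pair; an ``N`` inside a barcode also lands here), ``grna_mismatch`` and
    ``target_length``.
    """
    min_len = len(LEFT_FLANK) + GRNA_LEN + len(BSMBI_1) + BARCODE1_LEN + len(BSMBI_2) \
        + BARCODE2_LEN + len(TARGET_PREFIX) + len(TARGET_SUFFIX) + len(RIGHT_FLANK)
    if len(read) <= min_len:
        return None, "too_short"
    p = len(LEFT_FLANK)
    grna = read[p:p + GRNA_LEN]
    p += GRNA_LEN + len(BSMBI_1)
    bc1 = read[p:p + BARCODE1_LEN]
    p += BARCODE1_LEN + len(BSMBI_2)
    bc2 = read[p:p + BARCODE2_LEN]
    p += BARCODE2_LEN + len(TARGET_PREFIX)
    target = read[p:len(read) - len(TARGET_SUFFIX) - len(RIGHT_FLANK)]
    oligo_id = design.lookup(bc1, bc2)
    if oligo_id is None:
        return None, "barcode"
    row = design.oligo(oligo_id)
    if any(a != b and a != "N" for a, b in zip(grna, row.grna)):
        return None, "grna_mismatch"
    if len(target) != len(row.target):
        return None, "target_length"
    return ParsedRead(oligo_id, grna, target), None


def call_edited(target_region: str, designed_target: str, editor: str,
                window: tuple[int, int] | None = None):
    """Was this read edited at the designed target?

    Compares the observed target segment to the designed one at editable
    positions (designed A for ABE, designed C for CBE) of the 20-nt
    protospacer; edited means at least one canonical conversion (A->G or
    C->T). ``window`` restricts editable positions to a 1-based inclusive
    protospacer range. Returns True/False, or None when the read carries an
    ``N`` at an editable position and must be excluded from both counts.
    """
    src, dst = _CONVERSION[editor.upper()]
    lo, hi = (1, GRNA_LEN) if window is None else window
    edited = False
    for pos in range(lo - 1, min(hi, GRNA_LEN, len(designed_target))):
        if designed_target[pos] != src:
            continue
        obs = target_region[pos]
        if obs == "N":
            return None
        if obs == dst:
            edited = True
    return edited


def quantify_reads(fastq_path, design: LibraryDesign, editor: str,
                   window: tuple[int, int] | None = None,
                   quality_threshold: int = QUALITY_MASK_THRESHOLD) -> pd.DataFrame:
    """Count valid and edited reads per oligo for one replicate FASTQ.

    Returns a frame indexed like the design with ``valid_reads`` and
    ``edited_reads`` plus a QC attribute ``attrs['drop_reasons']``.
    """
    valid = {oid: 0 for oid in design.table["oligo_id"]}
    edited = dict(valid)
    reasons: dict[str, int] = {}
    total = 0
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        total += 1
        masked = mask_low_quality(str(rec.seq).upper(),
                                  rec.letter_annotations["phred_quality"],
                                  quality_threshold)
        parsed, reason = parse_and_validate(masked, design)
        if parsed is None:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        call = call_edited(parsed.target_region, design.oligo(parsed.oligo_id).target,
                           editor, window)
        if call is None:
            reasons["n_at_editable"] = reasons.get("n_at_editable", 0) + 1
            continue
        valid[parsed.oligo_id] += 1
        if call:
            edited[parsed.oligo_id] += 1
    out = pd.DataFrame({
        "oligo_id": list(valid),
        "valid_reads": list(valid.values()),
        "edited_reads": [edited[k] for k in valid],
    })
    out.attrs["drop_reasons"] = reasons
    out.attrs["total_reads"] = total
    return out


def compute_efficiency(valid_reads: int, edited_reads: int,
                       min_reads: int = MIN_VALID_READS) -> float | None:
    """editing efficiency = edited / valid; None when the pair is dropped."""
    if edited_reads < 0 or valid_reads < 0 or edited_reads > valid_reads:
        raise ValueError("need 0 <= edited_reads <= valid_reads")
    if valid_reads < min_reads:
        return None
    return edited_reads / valid_reads


def merge_replicates(r1: float | None, r2: float | None,
                     missing_policy: str = "drop") -> float | None:
    """Average two replicate efficiencies.

    ``missing_policy`` controls a single missing replicate: ``drop`` discards
    the pair, ``single`` keeps the surviving value.
    """
    if r1 is None and r2 is None:
        return None
    if r1 is None or r2 is None:
        if missing_policy == "single":
            return r1 if r1 is not None else r2
        if missing_policy == "drop":
            return None
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return (r1 + r2) / 2.0


def compute_off_on_ratio(off_merged: float, on_merged: float) -> float:
    """off:on-target ratio; larger than 1 is allowed (kept for analytics)."""
    if on_merged is None or on_merged <= 0:
        raise ZeroDivisionError("on-target efficiency is zero or missing")
    return off_merged / on_merged


def screen_quantify(design: LibraryDesign, fastq_rep1, fastq_rep2, editor: str,
                    window: tuple[int, int] | None = None,
                    min_reads: int = MIN_VALID_READS,
                    missing_policy: str = "drop") -> pd.DataFrame:
    """Full per-pair quantification across two replicates.

    Returns the efficiency table: one row per oligo with replicate counts and
    efficiencies, the merged efficiency, and (for off-targets whose group has
    a valid on-target with nonzero efficiency) the off:on-target ratio.
    """
    counts = []
    for path in (fastq_rep1, fastq_rep2):
        counts.append(quantify_reads(path, design, editor, window).set_index("oligo_id"))
    tbl = design.table[["oligo_id", "group_id", "mutation_type"]].copy()
    for rep, cnt in enumerate(counts, start=1):
        tbl[f"valid_r{rep}"] = cnt["valid_reads"].reindex(tbl["oligo_id"]).to_numpy()
        tbl[f"edited_r{rep}"] = cnt["edited_reads"].reindex(tbl["oligo_id"]).to_numpy()
        tbl[f"eff_r{rep}"] = [
            compute_efficiency(v, e, min_reads)
            for v, e in zip(tbl[f"valid_r{rep}"], tbl[f"edited_r{rep}"])
        ]
    tbl["merged_eff"] = [
        merge_replicates(r1, r2, missing_policy)
        for r1, r2 in zip(tbl["eff_r1"], tbl["eff_r2"])
    ]
    on_eff = {}
    for row in tbl[tbl["mutation_type"] == "on"].itertuples():
        on_eff[row.group_id] = row.merged_eff
    ratios, flags = [], []
    for row in tbl.itertuples():
        on = on_eff.get(row.group_id)
        if row.merged_eff is None or on is None or on <= 0:
            ratios.append(np.nan)
            flags.append("missing" if row.merged_eff is None else "no_on_target")
        else:
            ratios.append(row.merged_eff / on)
            flags.append("ok")
    tbl["off_on_ratio"] = ratios
    tbl["qc_flag"] = flags
    return tbl.reset_index(drop=True)
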