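"""Synthetic screen generator with known ground truth.

Emulates the structure of the gRNA-target pair screen end to end: grouped
library designs (one on-target plus designed mismatch / insertion / deletion /
mixed variants per gRNA group), replicate editing efficiencies, and amplicon
reads in the oligo layout, so that quantification, statistics and the
regression model can all be exercised against a planted truth.

The effect model is deliberately simple and is a statistical stand-in for the
screen, not a claim about editing biology: each mutated protospacer position
p carries a retention factor pi(p) in (0, 1], each event class a multiplier,
and the true off:on ratio of a variant is the product over its events. The
default pi is position-tolerant over positions 1-10 and declines toward the
PAM, echoing the positional tolerance the screens report; replicate
efficiencies add independent Gaussian noise so the inter-replicate
correlation is high but imperfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import screenproc as sp
from .seqrep import GuideTargetPair, classify_mutation_type

BASES = "ACGT"

#: per-group designed variant counts; mismatch-heavy like the screen library
DEFAULT_VARIANTS_PER_GROUP = {
    "1mis": 4, "2mis": 2, "3mis": 1,
    "1ins": 1, "2ins": 1,
    "1del": 1, "2del": 1,
    "mix": 1,
}

DEFAULT_TYPE_MULTIPLIER = {"mis": 1.0, "ins": 0.9, "del": 0.7}


def default_positional_penalty() -> np.ndarray:
    """Retention factor pi(p), p = 1..20 from the 5' end of the protospacer.

    Mutations at PAM-distal positions 1-10 are well tolerated; tolerance
    declines linearly through the seed region toward the PAM.
    """
    pi = np.empty(20)
    pi[:10] = 0.95
    pi[10:] = np.linspace(0.90, 0.45, 10)
    return pi


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_groups: int = 250
    variants_per_group: dict = field(default_factory=lambda: dict(DEFAULT_VARIANTS_PER_GROUP))
    positional_penalty: np.ndarray = field(default_factory=default_positional_penalty)
    type_multiplier: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MULTIPLIER))
    on_eff_beta_a: float = 5.0
    on_eff_beta_b: float = 2.0
    replicate_noise_sd: float = 0.02
    reads_per_pair: int = 150
    barcode_corruption_rate: float = 0.0
    low_quality_rate: float = 0.002
    editor: str = "ABE"
    editing_window: tuple[int, int] = (3, 9)

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# library generation


def _random_protospacer(rng: np.random.Generator, editor: str, window: tuple[int, int]) -> str:
    """A random 20-mer guaranteed to carry an editable base in the window."""
    editable = "A" if editor.upper() == "ABE" else "C"
    lo, hi = window
    while True:
        proto = "".join(rng.choice(list(BASES), size=20))
        if editable in proto[lo - 1:hi]:
            return proto


def _apply_events(proto_pam: str, mismatches, insertions, deletions, rng):
    """Build designed aligned strings from protospacer-coordinate events.

    ``mismatches``/``deletions`` are 1-based protospacer positions; an
    insertion at position p places the extra target base immediately before
    position p (a gap in the guide).
    """
    guide_cols = list(proto_pam)
    off_cols = list(proto_pam)
    for p in mismatches:
        old = off_cols[p - 1]
        off_cols[p - 1] = rng.choice([b for b in BASES if b != old])
    for p in deletions:
        off_cols[p - 1] = "-"
    for p in sorted(insertions, reverse=True):
        guide_cols.insert(p - 1, "-")
        off_cols.insert(p - 1, rng.choice(list(BASES)))
    return "".join(guide_cols), "".join(off_cols)


def _variant_events(mtype: str, rng: np.random.Generator):
    """Sample the event positions for one designed variant."""
    if mtype.endswith("mis"):
        k = int(mtype[0])
        return sorted(rng.choice(20, size=k, replace=False) + 1), [], []
    if mtype.endswith("ins"):
        k = int(mtype[0])
        return [], sorted(rng.choice(20, size=k, replace=False) + 1), []
    if mtype.endswith("del"):
        k = int(mtype[0])
        return [], [], sorted(rng.choice(20, size=k, replace=False) + 1)
    if mtype == "mix":
        n_mis = int(rng.integers(1, 3))
        indel_is_ins = bool(rng.integers(0, 2))
        pos = rng.choice(20, size=n_mis + 1, replace=False) + 1
        mis, ind = sorted(pos[:n_mis]), [int(pos[-1])]
        return (mis, ind, []) if indel_is_ins else (mis, [], ind)
    raise ValueError(f"unknown designed mutation type {mtype!r}")


def generate_library(config: GeneratorConfig):
    """Generate the designed library.

    Returns ``(design, pairs, truth)``: a :class:`~beoff.screenproc.LibraryDesign`,
    the corresponding list of :class:`~beoff.seqrep.GuideTargetPair`, and a
    truth frame with one row per oligo carrying its designed events.
    """
    rng = np.random.default_rng(config.seed)
    rows, pairs, truth_rows = [], [], []
    barcodes_seen = set()

    def fresh_barcode(length: int) -> str:
        while True:
            bc = "".join(rng.choice(list(BASES), size=length))
            if bc not in barcodes_seen:
                barcodes_seen.add(bc)
                return bc

    for gi in range(config.n_groups):
        group_id = f"g{gi:05d}"
        proto = _random_protospacer(rng, config.editor, config.editing_window)
        pam = rng.choice(list(BASES)) + "GG"
        guide = proto + pam
        variants = [("on", [], [], [])]
        for mtype, count in config.variants_per_group.items():
            for _ in range(count):
                mis, ins, dele = _variant_events(mtype, rng)
                variants.append((mtype, mis, ins, dele))
        for vi, (mtype, mis, ins, dele) in enumerate(variants):
            ag, ao = _apply_events(guide, mis, ins, dele, rng)
            off = ao.replace("-", "")
            oligo_id = f"{group_id}_v{vi:02d}"
            pair = GuideTargetPair(group_id, guide, off, ag, ao, mtype)
            pairs.append(pair)
            rows.append({
                "oligo_id": oligo_id,
                "group_id": group_id,
                "grna": proto,
                "barcode1": fresh_barcode(sp.BARCODE1_LEN),
                "barcode2": fresh_barcode(sp.BARCODE2_LEN),
                "target": off[:-2],  # protospacer + degenerate PAM base
                "offtarget_seq": off,
                "aligned_guide": ag,
                "aligned_off": ao,
                "mutation_type": mtype,
            })
            truth_rows.append({
                "oligo_id": oligo_id,
                "group_id": group_id,
                "mutation_type": mtype,
                "mismatch_positions": ";".join(map(str, mis)),
                "insertion_positions": ";".join(map(str, ins)),
                "deletion_positions": ";".join(map(str, dele)),
            })
    design = sp.LibraryDesign(pd.DataFrame(rows))
    return design, pairs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# efficiencies


def true_ratio(mis, ins, dele, config: GeneratorConfig) -> float:
    """Planted off:on ratio: product of positional retention x class multiplier."""
    pi = config.positional_penalty
    mult = config.type_multiplier
    r = 1.0
    for p in mis:
        r *= pi[p - 1] * mult["mis"]
    for p in ins:
        r *= pi[p - 1] * mult["ins"]
    for p in dele:
        r *= pi[p - 1] * mult["del"]
    return float(np.clip(r, 0.0, 1.0))


def _parse_positions(s: str) -> list[int]:
    return [int(x) for x in s.split(";")] if s else []


def generate_efficiencies(design: sp.LibraryDesign, truth: pd.DataFrame,
                          config: GeneratorConfig) -> pd.DataFrame:
    """Planted efficiencies and noisy replicates for every oligo.

    On-target efficiency is Beta-distributed per group; each off-target's
    true efficiency is its planted ratio times the group's on-target
    efficiency; replicates add independent Gaussian noise, clipped to [0, 1].
    Off-targets whose protospacer lacks any editable base get efficiency 0,
    matching what a screen could observe for them.
    """
    rng = np.random.default_rng(config.seed + 1)
    editable = "A" if config.editor.upper() == "ABE" else "C"
    on_eff = {}
    for group_id in truth["group_id"].unique():
        on_eff[group_id] = float(rng.beta(config.on_eff_beta_a, config.on_eff_beta_b))
    out = []
    for row in truth.itertuples():
        mis = _parse_positions(row.mismatch_positions)
        ins = _parse_positions(row.insertion_positions)
        dele = _parse_positions(row.deletion_positions)
        ratio = 1.0 if row.mutation_type == "on" else true_ratio(mis, ins, dele, config)
        dsg = design.oligo(row.oligo_id)
        has_editable = editable in dsg.target[:20]
        eff = ratio * on_eff[row.group_id] if has_editable else 0.0
        r1 = float(np.clip(eff + rng.normal(0, config.replicate_noise_sd), 0, 1))
        r2 = float(np.clip(eff + rng.normal(0, config.replicate_noise_sd), 0, 1))
        out.append({
            "oligo_id": row.oligo_id,
            "group_id": row.group_id,
            "mutation_type": row.mutation_type,
            "true_ratio": ratio if has_editable else 0.0,
            "true_efficiency": eff,
            "has_editable": has_editable,
            "eff_r1": r1,
            "eff_r2": r2,
        })
    df = pd.DataFrame(out)
    merged = (df["eff_r1"] + df["eff_r2"]) / 2.0
    df["merged_eff"] = merged
    on_merged = df[df["mutation_type"] == "on"].set_index("group_id")["merged_eff"]
    df["off_on_ratio"] = merged / df["group_id"].map(on_merged).to_numpy()
    return df


# ---------------------------------------------------------------------------
# reads


def _edit_target(target: str, editor: str) -> str:
    """A fully converted read: every editable protospacer base is converted."""
    src, dst = {"ABE": ("A", "G"), "CBE": ("C", "T")}[editor.upper()]
    proto = target[:20].replace(src, dst)
    return proto + target[20:]


def generate_reads(design: sp.LibraryDesign, efficiencies: pd.DataFrame,
                   config: GeneratorConfig, fastq_path, replicate: int) -> dict:
    """Write one replicate's FASTQ; returns bookkeeping counts.

    Each oligo emits ``reads_per_pair`` reads; the number of edited reads is
    binomial at the replicate's planted efficiency. Barcode corruption
    substitutes one barcode base at the configured rate; low-quality bases
    get Q2 (masked downstream), all others Q40.
    """
    rng = np.random.default_rng(config.seed + 100 + replicate)
    eff_col = f"eff_r{replicate}"
    n_corrupted = n_reads = n_lowq_bases = n_bases = 0
    with open(fastq_path, "w") as fh:
        for row in efficiencies.itertuples():
            oligo = design.build_oligo_sequence(row.oligo_id)
            dsg = design.oligo(row.oligo_id)
            t0 = (len(sp.LEFT_FLANK) + sp.GRNA_LEN + len(sp.BSMBI_1) + sp.BARCODE1_LEN
                  + len(sp.BSMBI_2) + sp.BARCODE2_LEN + len(sp.TARGET_PREFIX))
            edited_target = _edit_target(dsg.target, config.editor)
            eff = getattr(row, eff_col)
            n = config.reads_per_pair
            k = int(rng.binomial(n, eff))
            for i in range(n):
                seq = oligo
                if i < k:
                    seq = seq[:t0] + edited_target + seq[t0 + len(dsg.target):]
                if config.barcode_corruption_rate > 0 and rng.random() < config.barcode_corruption_rate:
                    b0 = len(sp.LEFT_FLANK) + sp.GRNA_LEN + len(sp.BSMBI_1)
                    j = int(rng.integers(b0, b0 + sp.BARCODE1_LEN))
                    seq = seq[:j] + str(rng.choice([b for b in BASES if b != seq[j]])) + seq[j + 1:]
                    n_corrupted += 1
                lowq = rng.random(len(seq)) < config.low_quality_rate
                quals = np.where(lowq, 2, 40)
                n_lowq_bases += int(lowq.sum())
                n_bases += len(seq)
                n_reads += 1
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@r{replicate}_{row.oligo_id}_{i}\n{seq}\n+\n{qstr}\n")
    return {
        "n_reads": n_reads,
        "n_corrupted_barcode": n_corrupted,
        "lowq_fraction": n_lowq_bases / max(n_bases, 1),
    }


def generate_screen(config: GeneratorConfig, outdir=None):
    """Library + efficiencies in one call; reads only when ``outdir`` given."""
    design, pairs, truth = generate_library(config)
    eff = generate_efficiencies(design, truth, config)
    artifacts = {"design": design, "pairs": pairs, "truth": truth, "efficiencies": eff}
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep in (1, 2):
            path = outdir / f"reads_rep{rep}.fastq"
            stats = generate_reads(design, eff, config, path, rep)
            artifacts[f"reads_rep{rep}"] = path
            artifacts[f"read_stats_rep{rep}"] = stats
    return artifacts


def benchmark_dataset(config: GeneratorConfig):
    """The pair dataset the model benchmark trains on.

    Regression targets are the *observed* (replicate-averaged, noisy)
    off:on ratios; the planted ``true_ratio`` column stays available for
    recovery checks against generator truth.
    """
    design, pairs, truth = generate_library(config)
    eff = generate_efficiencies(design, truth, config)
    off_mask = (eff["mutation_type"] != "on") & np.isfinite(eff["off_on_ratio"])
    by_id = {p_id: i for i, p_id in enumerate(truth["oligo_id"])}
    keep_pairs = [pairs[by_id[oid]] for oid in eff.loc[off_mask, "oligo_id"]]
    sub = eff[off_mask].reset_index(drop=True)
    return keep_pairs, sub
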