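"""Readers/writers for external formats and the canonical in-memory data model.

Coordinate conventions
----------------------
VCF positions are 1-based; all interval logic is 0-based half-open (BED
convention). Conversion between the two happens in exactly one place,
:func:`pos1_to_pos0`, so there is a single source of off-by-one truth.

Variant identity is the exact key ``chrom:pos:ref:alt``; inputs are assumed
pre-normalised (no left-alignment is attempted).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    EmptyCohortError,
    FormatError,
    VcfParseError,
)

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "SampleTable",
    "EnhancerGeneMap",
    "AUTOSOMES",
    "EFFECT_CLASSES",
    "RESULT_COLUMNS",
    "pos1_to_pos0",
    "read_vcf",
    "write_vcf",
    "read_sample_table",
    "write_sample_table",
    "read_enhancer_map",
    "write_enhancer_map",
    "merge_intervals",
    "read_annotations",
    "write_annotations",
    "attach_annotations",
    "write_results",
    "read_results",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(
    f"chr{i}" for i in range(1, 23)
)

EFFECT_CLASSES = frozenset(
    {"HIGH", "MODERATE", "LOW", "synonymous", "TF_binding_site_variant", "other"}
)

#: Deterministic column order of the association result table.
RESULT_COLUMNS = [
    "set_id",
    "flavor",
    "test",
    "n_variants",
    "statistic",
    "p",
    "p_bonf",
    "q_bh",
    "carriers_case",
    "n_case",
    "carriers_ctrl",
    "n_ctrl",
    "risk_ratio",
    "fallback_flag",
    "insufficient_flag",
]


def pos1_to_pos0(pos1: int) -> int:
    """Convert a 1-based (VCF) position to a 0-based (BED) coordinate."""
    return pos1 - 1


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant and its per-variant annotations.

    ``pop_af``/``cons_score``/``mean_depth`` are ``None`` when absent;
    ``effect_class`` is ``None`` when unannotated.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    pop_af: float | None = None
    cons_score: float | None = None
    effect_class: str | None = None
    missing_rate: float = 0.0
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise FormatError(f"pop_af out of [0,1]: {self.pop_af}")
        if self.cons_score is not None and not 0.0 <= self.cons_score <= 1.0:
            raise FormatError(f"cons_score out of [0,1]: {self.cons_score}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def pos0(self) -> int:
        return pos1_to_pos0(self.pos)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix; the substrate of every test.

    ``dosages`` is a float array with entries in {0, 1, 2} and ``nan`` for
    missing calls.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosages.shape != (n, m):
            raise FormatError(
                f"dosage shape {self.dosages.shape} != ({n} samples, {m} variants)"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise FormatError("dosages must be 0/1/2 or missing (nan)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_missing_rates(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rates(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        s = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=int)
        )
        v = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=int)
        )
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s],
            variants=[self.variants[j] for j in v],
            dosages=self.dosages[np.ix_(s, v)],
            meta=dict(self.meta),
        )


@dataclass
class SampleTable:
    """Phenotype + covariates: case/control status, sex, 10 PC eigenvectors."""

    sample_ids: list[str]
    status: np.ndarray  # 1 = case, 0 = control
    sex: np.ndarray | None = None
    pcs: np.ndarray | None = None  # n x 10

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample_ids must be unique")
        self.status = np.asarray(self.status, dtype=float)
        if not np.isin(self.status, (0.0, 1.0)).all():
            raise FormatError("status must be binary (case=1 / control=0)")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=float)
        if self.pcs is not None:
            self.pcs = np.asarray(self.pcs, dtype=float)
            if self.pcs.shape != (len(self.sample_ids), 10):
                raise FormatError(
                    f"pcs must be n x 10, got {self.pcs.shape}"
                )

    @property
    def n_case(self) -> int:
        return int(self.status.sum())

    @property
    def n_ctrl(self) -> int:
        return int((1 - self.status).sum())

    def covariates(self) -> np.ndarray | None:
        """Covariate design (sex + PCs, no intercept) or None when absent."""
        cols = []
        if self.sex is not None:
            cols.append(self.sex[:, None])
        if self.pcs is not None:
            cols.append(self.pcs)
        if not cols:
            return None
        return np.hstack(cols)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SampleTable":
        idx = np.asarray(idx)
        return SampleTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            status=self.status[idx],
            sex=None if self.sex is None else self.sex[idx],
            pcs=None if self.pcs is None else self.pcs[idx],
        )

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Reorder/select rows to match a genotype matrix's sample order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise FormatError(f"sample {exc.args[0]!r} absent from sample table")
        return self.subset(idx)


@dataclass
class EnhancerGeneMap:
    """One aggregation unit: a gene's (or pathway's) merged enhancer intervals."""

    set_id: str
    intervals: list[tuple[str, int, int]]  # (chrom, start0, end0), half-open
    flavor: str = "tissue_agnostic"

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise FormatError(
                    f"{self.set_id}: interval start {start} >= end {end}"
                )
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        return any(
            c == chrom and start <= pos0 < end for c, start, end in self.intervals
        )


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union of half-open intervals; overlapping or book-ended runs collapse.

    Idempotent and order-independent; output sorted by (chrom, start).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        runs = sorted(by_chrom[chrom])
        cur_s, cur_e = runs[0]
        for s, e in runs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    region_filter: Sequence[tuple[str, int, int]] | None = None,
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a dosage matrix.

    Only biallelic autosomal records are retained; multi-allelic and
    non-autosomal records are dropped and counted in
    ``meta["vcf_drop_counts"]``. Missing GT maps to nan dosage.

    ``region_filter`` optionally restricts to variants whose 0-based
    position falls inside any of the given (chrom, start0, end0) intervals.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise EmptyCohortError(f"{path}: VCF contains no samples")

    drop_counts = {"multiallelic": 0, "non_autosomal": 0, "outside_regions": 0}
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            if len(rec.ALT) != 1:
                drop_counts["multiallelic"] += 1
                continue
            if rec.CHROM not in AUTOSOMES:
                drop_counts["non_autosomal"] += 1
                continue
            pos0 = pos1_to_pos0(rec.POS)
            if region_filter is not None and not any(
                c == rec.CHROM and s <= pos0 < e for c, s, e in region_filter
            ):
                drop_counts["outside_regions"] += 1
                continue
            dos = np.empty(len(samples), dtype=float)
            for i, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]  # last element is the phased flag
                if any(a < 0 for a in alleles):
                    dos[i] = np.nan
                else:
                    dos[i] = float(sum(1 for a in alleles if a > 0))
            variants.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    missing_rate=float(np.isnan(dos).mean()),
                )
            )
            rows.append(dos)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF at data record {record_no + 1}: {exc}"
        ) from exc

    dosages = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0), dtype=float)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        variants=variants,
        dosages=dosages,
        meta={"vcf_drop_counts": drop_counts, "vcf_path": str(path)},
    )


def write_vcf(gm: GenotypeMatrix, path: str, extra_headers: Sequence[str] = ()) -> None:
    """Serialise a genotype matrix as a minimal plain-text VCF (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_headers:
            fh.write(line.rstrip("\n") + "\n")
        chroms = sorted({v.chrom for v in gm.variants})
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = sorted(
            range(gm.n_variants),
            key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos),
        )
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            v = gm.variants[j]
            gts = [
                "./." if math.isnan(d) else gt_of[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

_PC_COLS = [f"PC{i}" for i in range(1, 11)]


def read_sample_table(path: str) -> SampleTable:
    """TSV with header: sample_id, status (case|control or 1|0), sex, PC1..PC10.

    ``sex`` and PC columns are optional; when PCs are present all ten must be.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise FormatError(f"{path}: sample table needs sample_id and status columns")
    status_map = {"case": 1.0, "control": 0.0, "1": 1.0, "0": 0.0}
    try:
        status = np.array(
            [status_map[str(s).strip()] for s in df["status"]], dtype=float
        )
    except KeyError as exc:
        raise FormatError(f"{path}: unrecognised status value {exc.args[0]!r}")
    sex = df["sex"].to_numpy(dtype=float) if "sex" in df.columns else None
    pcs = None
    present_pcs = [c for c in _PC_COLS if c in df.columns]
    if present_pcs:
        if len(present_pcs) != 10:
            raise FormatError(f"{path}: expected 10 PC columns, found {len(present_pcs)}")
        pcs = df[_PC_COLS].to_numpy(dtype=float)
    return SampleTable(
        sample_ids=df["sample_id"].tolist(), status=status, sex=sex, pcs=pcs
    )


def write_sample_table(st: SampleTable, path: str, header_comments: Sequence[str] = ()) -> None:
    cols: dict[str, object] = {
        "sample_id": st.sample_ids,
        "status": ["case" if s == 1 else "control" for s in st.status],
    }
    if st.sex is not None:
        cols["sex"] = st.sex.astype(int)
    if st.pcs is not None:
        for i, c in enumerate(_PC_COLS):
            cols[c] = st.pcs[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Enhancer map
# ---------------------------------------------------------------------------

def read_enhancer_map(path: str) -> list[EnhancerGeneMap]:
    """TSV of (set_id, chrom, start0, end0, flavor); rows grouped by set.

    Intervals within a set are merged when overlapping or book-ended;
    duplicate rows collapse under the union. Row order determines set order.
    """
    sets: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "set_id":  # optional header
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            set_id, chrom = parts[0], parts[1]
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: coordinates must be integers")
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            flavor = parts[4] if len(parts) > 4 and parts[4] else "tissue_agnostic"
            key = (set_id, flavor)
            if key not in sets:
                sets[key] = []
                order.append(key)
            sets[key].append((chrom, start, end))
    return [
        EnhancerGeneMap(set_id=set_id, intervals=sets[(set_id, flavor)], flavor=flavor)
        for set_id, flavor in order
    ]


def write_enhancer_map(maps: Sequence[EnhancerGeneMap], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tchrom\tstart0\tend0\tflavor\n")
        for m in maps:
            for chrom, start, end in m.intervals:
                fh.write(f"{m.set_id}\t{chrom}\t{start}\t{end}\t{m.flavor}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANN_FIELDS = ("pop_af", "cons_score", "effect_class", "mean_depth")


def read_annotations(path: str) -> dict[str, dict]:
    """Per-variant annotations keyed ``chrom:pos:ref:alt``.

    TSV columns: chrom, pos1, ref, alt, pop_af, cons_score, effect_class and
    optionally mean_depth; "." or empty marks an absent value. Exact-key join
    only. Duplicate keys must agree, else :class:`DuplicateKeyError`.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = {"chrom", "pos1", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation table needs columns {sorted(required)}")

    def _num(value: str) -> float | None:
        return None if value in ("", ".") else float(value)

    def _cls(value: str) -> str | None:
        return None if value in ("", ".") else value

    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        key = f"{row.chrom}:{int(row.pos1)}:{row.ref}:{row.alt}"
        entry = {
            "pop_af": _num(getattr(row, "pop_af", ".")),
            "cons_score": _num(getattr(row, "cons_score", ".")),
            "effect_class": _cls(getattr(row, "effect_class", ".")),
            "mean_depth": _num(getattr(row, "mean_depth", ".")),
        }
        if key in out and out[key] != entry:
            raise DuplicateKeyError(
                f"{path}: conflicting duplicate annotation for {key}"
            )
        out[key] = entry
    return out


def write_annotations(ann: Mapping[str, Mapping], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tref\talt\tpop_af\tcons_score\teffect_class\tmean_depth\n")
        for key, entry in ann.items():
            chrom, pos1, ref, alt = key.split(":")
            vals = []
            for f in _ANN_FIELDS:
                v = entry.get(f)
                if v is None:
                    vals.append(".")
                elif isinstance(v, float):
                    vals.append(f"{v:.12g}")
                else:
                    vals.append(str(v))
            fh.write(f"{chrom}\t{pos1}\t{ref}\t{alt}\t" + "\t".join(vals) + "\n")


def attach_annotations(gm: GenotypeMatrix, ann: Mapping[str, Mapping]) -> GenotypeMatrix:
    """Join annotations onto variants by exact key; misses stay absent.

    Join failures are recorded in ``meta["annotation_misses"]``, never fatal
    (conservation tracks are sparse by nature).
    """
    new_variants = []
    misses = 0
    for v in gm.variants:
        entry = ann.get(v.key)
        if entry is None:
            misses += 1
            new_variants.append(v)
        else:
            new_variants.append(
                replace(
                    v,
                    pop_af=entry.get("pop_af"),
                    cons_score=entry.get("cons_score"),
                    effect_class=entry.get("effect_class"),
                    mean_depth=entry.get("mean_depth"),
                )
            )
    meta = dict(gm.meta)
    meta["annotation_misses"] = misses
    return GenotypeMatrix(
        sample_ids=gm.sample_ids, variants=new_variants, dosages=gm.dosages, meta=meta
    )


# ---------------------------------------------------------------------------
# Result table
# ---------------------------------------------------------------------------

def write_results(
    results: pd.DataFrame, path: str, header_comments: Sequence[str] = ()
) -> None:
    """Write the result table as TSV with deterministic column order.

    Floats are rendered with 12 significant digits so a round-trip read
    reproduces values; NaN serialises as ``NA``.
    """
    cols = [c for c in RESULT_COLUMNS if c in results.columns] + [
        c for c in results.columns if c not in RESULT_COLUMNS
    ]
    df = results[cols]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
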