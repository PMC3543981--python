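"""Genotype containers and readers/writers for VCF, PLINK and tabular data.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
SNPs, genotypes coded as alternate-allele counts in {0, 1, 2} with an
explicit missing sentinel (:data:`MISSING`, stored as -1 in an int16
array).  A :class:`ReferencePanel` attaches one population label per
individual from an ordered set of K population names.

Supported on-disk dialects:

* VCF 4.x (biallelic SNP records, GT field; read via cyvcf2, written as
  plain text),
* PLINK binary ``.bed``/``.bim``/``.fam`` (SNP-major; read only),
* a minimal tab-separated "table" dialect: header row of variant IDs,
  one row per sample, entries 0/1/2/NA.

``merge_intersect`` merges cohorts genotyped on different platforms by
(chrom, pos) intersection with allele alignment and strand flipping, the
step that produces the common-marker set a multi-source reference panel
is built on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

MISSING: int = -1
_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, id, ref/alt alleles."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ParameterError(
                f"alleles must be single bases in ACGT, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise ParameterError(f"ref and alt alleles are identical: {self.ref}")

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T and C/G sites, whose strand cannot be resolved from alleles."""
        return self.alt == _COMPLEMENT[self.ref]


class GenotypeMatrix:
    """n samples x J variants of alt-allele counts with explicit missingness."""

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantRecord],
        G: np.ndarray,
    ) -> None:
        G = np.asarray(G, dtype=np.int16)
        if G.shape != (len(samples), len(variants)):
            raise DataError(
                f"genotype matrix shape {G.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        valid = (G == MISSING) | ((G >= 0) & (G <= 2))
        if not valid.all():
            raise DataError("genotypes must be 0, 1, 2 or missing")
        if len(set(samples)) != len(samples):
            raise DataError("duplicate sample IDs")
        self.samples = list(samples)
        self.variants = list(variants)
        self.G = G

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def J(self) -> int:
        return len(self.variants)

    def observed_mask(self) -> np.ndarray:
        return self.G != MISSING

    def snp_missing_rate(self) -> np.ndarray:
        """Fraction of samples missing, per variant."""
        if self.n == 0:
            return np.zeros(self.J)
        return (self.G == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        """Fraction of variants missing, per sample."""
        if self.J == 0:
            return np.zeros(self.n)
        return (self.G == MISSING).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing genotypes."""
        obs = self.observed_mask()
        counts = np.where(obs, self.G, 0).sum(axis=0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    # -- subsetting -----------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.variants, self.G[idx, :]
        )

    def take_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.samples, [self.variants[i] for i in idx], self.G[:, idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.G, other.G)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix(n={self.n}, J={self.J})"


@dataclass
class ReferencePanel:
    """Genotypes plus one documented population label per individual.

    ``populations`` fixes the order of the K ancestral populations used
    throughout estimation (columns of Q, rows of allele-frequency
    matrices).
    """

    genotypes: GenotypeMatrix
    labels: list[str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.genotypes.n:
            raise DataError("one label per sample required")
        if not self.populations:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.populations = list(seen)
        missing = set(self.labels) - set(self.populations)
        if missing:
            raise DataError(f"labels not in population list: {sorted(missing)}")
        for pop in self.populations:
            if pop not in self.labels:
                raise DataError(f"population {pop!r} has no members")

    @property
    def K(self) -> int:
        return len(self.populations)

    def label_indices(self) -> np.ndarray:
        """Population index (into ``populations``) per sample."""
        lookup = {p: k for k, p in enumerate(self.populations)}
        return np.array([lookup[lab] for lab in self.labels], dtype=int)

    def members_of(self, population: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == population]

    def subset_populations(self, keep: Sequence[str]) -> "ReferencePanel":
        keep_set = set(keep)
        idx = [i for i, lab in enumerate(self.labels) if lab in keep_set]
        return ReferencePanel(
            self.genotypes.take_samples(idx),
            [self.labels[i] for i in idx],
            [p for p in self.populations if p in keep_set],
        )

    def drop_sample(self, i: int) -> "ReferencePanel":
        idx = [j for j in range(self.genotypes.n) if j != i]
        return ReferencePanel(
            self.genotypes.take_samples(idx),
            [self.labels[j] for j in idx],
            self.populations,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from ``path`` in one of {vcf, plink, table}.

    ``format=None`` infers the dialect from the file extension.  Only
    biallelic SNPs are accepted; multi-allelic or non-SNP records are
    skipped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    if format == "table":
        return _read_table(path)
    raise ParameterError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    """Write genotypes in one of {vcf, table}; re-readable to an equal matrix."""
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "vcf":
        _write_vcf(G, path)
    elif format == "table":
        _write_table(G, path)
    else:
        raise ParameterError(f"unsupported output format {format!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vcf":
        return "vcf"
    if suffix in {".bed", ".bim", ".fam"} or (
        path.with_suffix(".bed").exists() and not path.suffix
    ):
        return "plink"
    return "table"


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on parse failure
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or v.REF not in _BASES
            or v.ALT[0] not in _BASES
            or v.REF == v.ALT[0]
        ):
            skipped += 1
            continue
        vid = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        variants.append(VariantRecord(v.CHROM, v.POS, vid, v.REF, v.ALT[0]))
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        columns.append(col.astype(np.int16))
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not variants:
        raise DataError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(samples, variants, np.column_stack(columns))


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = []
    for v in G.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + G.samples) + "\n")
        for j, v in enumerate(G.variants):
            row = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", ".", "GT"]
            row += [gt_codes[int(g)] for g in G.G[:, j]]
            fh.write("\t".join(row) + "\n")


def _read_table(path: Path) -> GenotypeMatrix:
    if not Path(path).exists():
        raise DataError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataError(f"empty table file: {path}")
        ids = header.split("\t")[1:]
        variants = [_variant_from_table_id(vid, j) for j, vid in enumerate(ids)]
        samples: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ids) + 1:
                raise DataError(f"ragged row in {path}: {parts[0]!r}")
            samples.append(parts[0])
            rows.append(
                [MISSING if p in {"NA", ""} else int(p) for p in parts[1:]]
            )
    if not variants:
        raise DataError(f"no variants in table file {path}")
    G = np.array(rows, dtype=np.int16).reshape(len(samples), len(variants))
    return GenotypeMatrix(samples, variants, G)


def _variant_from_table_id(vid: str, j: int) -> VariantRecord:
    # dialect packs metadata as [id@]chrom:pos:ref:alt when available, else a bare id
    name, _, loc = vid.rpartition("@")
    parts = loc.split(":")
    if len(parts) == 4 and parts[1].isdigit():
        return VariantRecord(parts[0], int(parts[1]), name or vid, parts[2], parts[3])
    return VariantRecord("0", j + 1, vid, "A", "G")


def _write_table(G: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        ids = [f"{v.id}@{v.chrom}:{v.pos}:{v.ref}:{v.alt}" for v in G.variants]
        fh.write("sample\t" + "\t".join(ids) + "\n")
        for i, s in enumerate(G.samples):
            vals = ["NA" if g == MISSING else str(int(g)) for g in G.G[i, :]]
            fh.write(s + "\t" + "\t".join(vals) + "\n")


_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, A1-allele counts: 00 -> 2, 10 -> 1, 11 -> 0, 01 -> missing
_PLINK_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int16)


def _read_plink(path: Path) -> GenotypeMatrix:
    prefix = path.with_suffix("") if path.suffix in {".bed", ".bim", ".fam"} else path
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise DataError(f"missing PLINK file: {p}")
    samples = [line.split()[1] for line in fam.read_text().splitlines() if line.strip()]
    variants: list[VariantRecord] = []
    usable: list[int] = []
    skipped = 0
    for j, line in enumerate(bim.read_text().splitlines()):
        if not line.strip():
            continue
        chrom, vid, _cm, pos, a1, a2 = line.split()[:6]
        if a1 in _BASES and a2 in _BASES and a1 != a2:
            # a1 is the counted (alt) allele, a2 the reference allele
            variants.append(VariantRecord(chrom, int(pos), vid, a2, a1))
            usable.append(j)
        else:
            skipped += 1
    if skipped:
        logger.info("skipped %d non-SNP records in %s", skipped, bim)
    if not variants:
        raise DataError(f"no usable biallelic SNPs in {bim}")
    raw = bed.read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise DataError(f"{bed} is not a SNP-major PLINK .bed file")
    n = len(samples)
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    n_var_total = len(body) // bytes_per_variant
    body = body[: n_var_total * bytes_per_variant].reshape(n_var_total, bytes_per_variant)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    G = _PLINK_DECODE[codes.reshape(n_var_total, -1)[:, :n]]
    return GenotypeMatrix(samples, variants, G[usable, :].T)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a dict."""
    out: dict[str, str] = {}
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"label file {path} must have 2 columns, got {line!r}")
        out[parts[0]] = parts[1]
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_intersect(
    datasets: Sequence[GenotypeMatrix], keep_ambiguous: bool = False
) -> GenotypeMatrix:
    """Merge cohorts on the (chrom, pos) intersection of their variants.

    Alleles are aligned to the first dataset's ref/alt orientation:
    swapped ref/alt flips the allele count (g -> 2-g), an unambiguous
    complement match flips strand, and a swapped complement does both.
    Strand-ambiguous sites (A/T, C/G) cannot be oriented from alleles
    alone and are dropped unless ``keep_ambiguous`` (then matched by
    literal allele identity only).  Sites whose allele pairs are neither
    identical, swapped nor complementary are dropped, not errored.
    Samples are concatenated in dataset order.
    """
    if len(datasets) < 2:
        raise ParameterError("merge_intersect requires at least 2 datasets")
    all_samples = [s for d in datasets for s in d.samples]
    if len(set(all_samples)) != len(all_samples):
        raise DataError("duplicate sample IDs across datasets")

    ref = datasets[0]
    keymaps = [{(v.chrom, v.pos): j for j, v in enumerate(d.variants)} for d in datasets]
    kept_cols: list[int] = []
    aligned: list[list[np.ndarray]] = [[] for _ in datasets]
    n_dropped_ambiguous = 0
    n_dropped_mismatch = 0
    for j0, v0 in enumerate(ref.variants):
        key = (v0.chrom, v0.pos)
        if not all(key in km for km in keymaps[1:]):
            continue
        if v0.is_ambiguous and not keep_ambiguous:
            n_dropped_ambiguous += 1
            continue
        cols = [ref.G[:, j0]]
        ok = True
        for d, km in zip(datasets[1:], keymaps[1:]):
            v = d.variants[km[key]]
            g = d.G[:, km[key]]
            flip = _orientation(v0, v, allow_strand=not v0.is_ambiguous)
            if flip is None:
                ok = False
                break
            cols.append(np.where(g == MISSING, MISSING, 2 - g) if flip else g)
        if not ok:
            n_dropped_mismatch += 1
            continue
        kept_cols.append(j0)
        for lst, c in zip(aligned, cols):
            lst.append(np.asarray(c, dtype=np.int16))
    if n_dropped_ambiguous or n_dropped_mismatch:
        logger.info(
            "merge dropped %d strand-ambiguous and %d allele-mismatched sites",
            n_dropped_ambiguous,
            n_dropped_mismatch,
        )
    if not kept_cols:
        raise DataError("no variants shared by all datasets after allele alignment")
    variants = [ref.variants[j] for j in kept_cols]
    blocks = [np.column_stack(lst) for lst in aligned]
    return GenotypeMatrix(all_samples, variants, np.vstack(blocks))


def _orientation(v0: VariantRecord, v: VariantRecord, allow_strand: bool) -> bool | None:
    """Return False (same coding), True (flip g -> 2-g) or None (incompatible)."""
    if (v.ref, v.alt) == (v0.ref, v0.alt):
        return False
    if (v.ref, v.alt) == (v0.alt, v0.ref):
        return True
    if allow_strand:
        c0 = (_COMPLEMENT[v0.ref], _COMPLEMENT[v0.alt])
        if (v.ref, v.alt) == c0:
            return False
        if (v.ref, v.alt) == (c0[1], c0[0]):
            return True
    return None
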