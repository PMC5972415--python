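"""Reading and writing allele-depth data and applying SNP filters.

The in-memory container is :class:`CountMatrix`: an n-individuals by
L-loci pair of integer matrices, ``y`` (reference-allele read counts)
and ``d`` (total depths), with sample identifiers and per-locus
records. Depth zero marks a missing observation.

Inputs: VCF 4.x with a per-sample AD FORMAT field (biallelic SNPs), or
a pair of delimited matrices (reference counts + total depths) as
produced by tag-count pipelines that do not emit VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gusld")

__all__ = [
    "CountMatrix",
    "FilterSpec",
    "FormatError",
    "EmptyResultError",
    "read_vcf_ad",
    "read_tabular_counts",
    "write_tabular_counts",
    "apply_filters",
]


class FormatError(ValueError):
    """Input file does not carry the expected fields or shape."""


class EmptyResultError(RuntimeError):
    """No loci left after filtering."""


@dataclass
class CountMatrix:
    """Reference-read counts and depths for n samples at L biallelic SNPs.

    ``loci`` is a DataFrame with columns (id, chrom, pos, ref, alt);
    ``pos`` is 1-based as in VCF, or -1 when the source format carries
    no coordinates.
    """

    samples: list[str]
    loci: pd.DataFrame
    y: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        n, L = len(self.samples), len(self.loci)
        if self.y.shape != (n, L) or self.d.shape != (n, L):
            raise ValueError(
                f"count matrices must be ({n}, {L}); got {self.y.shape}, {self.d.shape}"
            )
        bad = np.argwhere((self.y < 0) | (self.d < 0) | (self.y > self.d))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"invalid counts (need 0 <= y <= d) at sample "
                f"{self.samples[i]!r}, locus {self.loci['id'].iloc[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def L(self) -> int:
        return len(self.loci)

    def pooled_freq(self) -> np.ndarray:
        """Read-pooled reference-allele proportion per locus."""
        tot = self.d.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.y.sum(axis=0) / np.maximum(tot, 1), np.nan)

    def missing_rate(self) -> np.ndarray:
        """Proportion of samples with zero depth per locus."""
        return (self.d == 0).mean(axis=0)


@dataclass(frozen=True)
class FilterSpec:
    """SNP retention thresholds.

    Loci are kept when the read-pooled minor allele frequency exceeds
    ``maf_min`` and the proportion of depth-zero samples is below
    ``max_missing``; pairs with fewer than ``min_pair_overlap``
    individuals observed at both loci are not estimated.
    """

    maf_min: float = 0.05
    max_missing: float = 0.25
    min_pair_overlap: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 1.0 and 0.0 <= self.max_missing <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


def read_vcf_ad(path: str, skip_multiallelic: bool = True) -> CountMatrix:
    """Read a VCF with per-sample allelic depths into a CountMatrix.

    ``y`` is the reference AD entry and ``d`` the sum of all AD
    entries; samples without AD (e.g. ./.) get ``y = d = 0``.
    Multiallelic records are skipped (with a logged count) or rejected
    depending on ``skip_multiallelic``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, ys, ds = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise FormatError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                "(pass skip_multiallelic=True to drop such records)"
            )
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(f"record {var.CHROM}:{var.POS} lacks the AD FORMAT field")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # missing AD encodes as negative sentinels
        if ad.shape[1] > 2:
            logger.warning(
                "record %s:%s carries %d AD values on a biallelic line; "
                "depth taken as their sum", var.CHROM, var.POS, ad.shape[1],
            )
        ids.append({
            "id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM, "pos": var.POS,
            "ref": var.REF, "alt": var.ALT[0],
        })
        ys.append(ad[:, 0])
        ds.append(ad.sum(axis=1))
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    if not ids:
        raise FormatError(f"no usable biallelic records in {path}")
    return CountMatrix(
        samples=samples,
        loci=pd.DataFrame(ids),
        y=np.stack(ys, axis=1),
        d=np.stack(ds, axis=1),
    )


def read_tabular_counts(ref_path: str, depth_path: str, sep: str = "\t") -> CountMatrix:
    """Read paired delimited matrices of reference counts and depths.

    Both files: first column sample identifiers, header row locus
    identifiers, integer cells; shapes and labels must match.
    """
    try:
        ref = pd.read_csv(ref_path, sep=sep, index_col=0)
        dep = pd.read_csv(depth_path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty or unparsable input: {exc}") from exc
    if ref.shape != dep.shape:
        raise FormatError(
            f"dimension mismatch: counts {ref.shape} vs depths {dep.shape}"
        )
    if list(ref.index) != list(dep.index) or list(ref.columns) != list(dep.columns):
        raise FormatError("sample/locus labels differ between the two matrices")
    loci = pd.DataFrame({
        "id": list(ref.columns),
        "chrom": [c.split(":")[0] if ":" in c else c for c in ref.columns],
        "pos": [int(c.split(":")[1]) if ":" in c and c.split(":")[1].isdigit() else -1
                for c in ref.columns],
        "ref": "A", "alt": "B",
    })
    return CountMatrix(
        samples=[str(s) for s in ref.index],
        loci=loci,
        y=ref.to_numpy(dtype=np.int64),
        d=dep.to_numpy(dtype=np.int64),
    )


def write_tabular_counts(cm: CountMatrix, ref_path: str, depth_path: str, sep: str = "\t") -> None:
    """Write a CountMatrix as the paired matrices read_tabular_counts reads."""
    cols = list(cm.loci["id"])
    pd.DataFrame(cm.y, index=cm.samples, columns=cols).to_csv(ref_path, sep=sep)
    pd.DataFrame(cm.d, index=cm.samples, columns=cols).to_csv(depth_path, sep=sep)


def apply_filters(cm: CountMatrix, spec: FilterSpec | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop loci failing the MAF / missingness thresholds.

    Returns the filtered matrix (surviving loci keep their original
    records) and a report listing each dropped locus with the reason.
    Raises :class:`EmptyResultError` if nothing survives.
    """
    spec = spec or FilterSpec()
    freq = cm.pooled_freq()
    maf = np.minimum(freq, 1.0 - freq)
    miss = cm.missing_rate()
    dropped = []
    keep = np.ones(cm.L, dtype=bool)
    for j in range(cm.L):
        reasons = []
        if not (maf[j] > spec.maf_min):  # also drops all-missing loci (NaN maf)
            reasons.append(f"maf<={spec.maf_min}")
        if miss[j] >= spec.max_missing:
            reasons.append(f"missing>={spec.max_missing}")
        if reasons:
            keep[j] = False
            dropped.append({
                "id": cm.loci["id"].iloc[j],
                "maf": maf[j], "missing": miss[j],
                "reason": ";".join(reasons),
            })
    report = pd.DataFrame(dropped, columns=["id", "maf", "missing", "reason"])
    if not keep.any():
        raise EmptyResultError("all loci removed by filters")
    out = CountMatrix(
        samples=cm.samples,
        loci=cm.loci.loc[keep].reset_index(drop=True),
        y=cm.y[:, keep],
        d=cm.d[:, keep],
    )
    return out, report
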