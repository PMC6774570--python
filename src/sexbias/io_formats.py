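"""SFS file I/O, VCF-to-SFS construction, and callable-length bookkeeping.

The SFS text dialect has three lines:

1. ``<n+1> <folded|unfolded>`` — number of frequency classes including
   both monomorphic ends, and the folding marker;
2. ``n+1`` whitespace-separated counts (monomorphic entries are
   written as 0; folded spectra must have zeros above ``n/2``);
3. ``n+1`` 0/1 mask tokens (1 = excluded from likelihoods; the
   monomorphic ends are always 1).

VCF input goes through cyvcf2: biallelic SNPs only, sites with more
than 5% missing genotypes dropped, remaining missingness absorbed by
hypergeometric projection onto a common sample size, folded by default
(no ancestral allele needed).  Callable lengths are adjusted by the
fraction of SNPs surviving the filters, so per-site rates stay
comparable after filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sfs_engine import SpectrumData, fold as fold_sfs

__all__ = ["CallableLength", "read_sfs", "write_sfs", "vcf_to_sfs"]

logger = logging.getLogger(__name__)


@dataclass
class CallableLength:
    """Callable bases and the SNP-retention adjustment."""

    raw_length: float
    retained_snp_fraction: float

    def __post_init__(self):
        if self.raw_length <= 0:
            raise ValueError("raw length must be positive")
        if not 0 < self.retained_snp_fraction <= 1:
            raise ValueError("retained fraction must be in (0, 1]")

    @property
    def adjusted_length(self) -> float:
        return self.raw_length * self.retained_snp_fraction


def write_sfs(s: SpectrumData, path) -> None:
    """Write a spectrum in the three-line text dialect (round-trip safe)."""
    n = s.n
    full = np.zeros(n + 1)
    maskv = np.ones(n + 1, dtype=int)
    if s.folded:
        full[1 : n // 2 + 1] = s.counts
        maskv[1 : n // 2 + 1] = s.mask.astype(int)
    else:
        full[1:n] = s.counts
        maskv[1:n] = s.mask.astype(int)
    with open(path, "w") as fh:
        fh.write(f"{n + 1} {'folded' if s.folded else 'unfolded'}\n")
        fh.write(" ".join("%.17g" % c for c in full) + "\n")
        fh.write(" ".join(str(m) for m in maskv) + "\n")


def _parse_error(path, lineno, msg):
    return ValueError(f"{path}:{lineno}: {msg}")


def read_sfs(path, L: float = 1.0, mu: float = 1.5e-8, chrom_class: str = "A") -> SpectrumData:
    """Read the three-line SFS dialect back into a :class:`SpectrumData`.

    ``L``, ``mu`` and ``chrom_class`` are not stored in the file and are
    supplied by the caller.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise _parse_error(path, len(lines), "expected 3 lines (header, counts, mask)")
    head = lines[0].split()
    if len(head) != 2 or head[1] not in ("folded", "unfolded"):
        raise _parse_error(path, 1, "header must be '<n+1> <folded|unfolded>'")
    try:
        dim = int(head[0])
    except ValueError:
        raise _parse_error(path, 1, f"bad dimension token {head[0]!r}") from None
    n = dim - 1
    if n < 2:
        raise _parse_error(path, 1, "need at least 2 chromosomes")
    folded = head[1] == "folded"
    toks = lines[1].split()
    if len(toks) != dim:
        raise _parse_error(path, 2, f"expected {dim} count tokens, got {len(toks)}")
    try:
        full = np.array([float(t) for t in toks])
    except ValueError:
        raise _parse_error(path, 2, "non-numeric count token") from None
    if np.any(full[1:n] < 0):
        raise _parse_error(path, 2, "negative polymorphic count")
    mtoks = lines[2].split()
    if len(mtoks) != dim:
        raise _parse_error(path, 3, f"mask length {len(mtoks)} != dimension {dim}")
    if any(t not in ("0", "1") for t in mtoks):
        raise _parse_error(path, 3, "mask tokens must be 0 or 1")
    maskv = np.array([t == "1" for t in mtoks])
    if folded:
        if np.any(full[n // 2 + 1 : n] != 0):
            raise _parse_error(path, 2, "folded spectrum has entries above n/2")
        counts = full[1 : n // 2 + 1]
        mask = maskv[1 : n // 2 + 1]
    else:
        counts = full[1:n]
        mask = maskv[1:n]
    return SpectrumData(
        counts, n, folded=folded, mask=mask, L=L, mu=mu, chrom_class=chrom_class
    )


# ---------------------------------------------------------------------------
# VCF -> SFS


def _load_bed(path):
    """0-based half-open exclusion intervals, per chromosome."""
    starts, ends = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise _parse_error(path, lineno, "BED needs chrom/start/end")
            c, a, b = parts[0], int(parts[1]), int(parts[2])
            starts.setdefault(c, []).append(a)
            ends.setdefault(c, []).append(b)
    return {
        c: (np.array(sorted(starts[c])), np.array([e for _, e in sorted(zip(starts[c], ends[c]))]))
        for c in starts
    }


def _in_bed(bed, chrom, pos0):
    if bed is None or chrom not in bed:
        return False
    starts, ends = bed[chrom]
    k = int(np.searchsorted(starts, pos0, side="right")) - 1
    return k >= 0 and pos0 < ends[k]


def _project_site(k: int, c: int, m: int) -> np.ndarray:
    """Expected class contributions of one site with k alt of c called
    alleles, projected to m; length m+1 including monomorphic ends."""
    j = np.arange(m + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            gammaln(k + 1) - gammaln(j + 1.0) - gammaln(k - j + 1.0)
            + gammaln(c - k + 1) - gammaln(m - j + 1.0) - gammaln(c - k - m + j + 1.0)
            - (gammaln(c + 1) - gammaln(m + 1.0) - gammaln(c - m + 1.0))
        )
    bad = (j > k) | (m - j > c - k)
    out = np.exp(np.where(bad, -np.inf, logp))
    return out


def vcf_to_sfs(
    vcf_path,
    raw_length: float,
    samples=None,
    chrom_class: str = "A",
    region: str = None,
    exclude_bed=None,
    max_missing: float = 0.05,
    fold: bool = True,
    project_to: int = None,
    mu: float = 1.5e-8,
):
    """Build an SFS from a VCF of biallelic SNPs.

    Filters follow the whole-genome protocol: multi-allelic records and
    non-SNPs are dropped, sites with more than ``max_missing`` missing
    genotypes are excluded, remaining missingness is absorbed by
    hypergeometric projection onto a common sample size
    (``project_to``, default the full diploid allele count), an
    optional BED exclusion mask is applied before counting, and the
    callable length is multiplied by the fraction of SNPs retained.
    Folded by default, so no ancestral allele is required.

    X-chromosomal input must come from female samples only (diploid X);
    haploid or mixed-ploidy genotype records are rejected rather than
    silently mis-counted.  Returns ``(SpectrumData, CallableLength)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), samples=list(samples) if samples else None)
    nsamp = len(vcf.samples)
    if nsamp == 0:
        raise ValueError("no samples selected from VCF")
    full_alleles = 2 * nsamp
    m = project_to if project_to is not None else full_alleles
    if not 2 <= m <= full_alleles:
        raise ValueError(f"projection target must be in [2, {full_alleles}]")
    bed = _load_bed(exclude_bed) if exclude_bed is not None else None
    acc = np.zeros(m + 1)
    seen = kept = 0
    any_alt = False
    contig_seen = False
    for v in vcf(region) if region else vcf:
        contig_seen = True
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        seen += 1
        if _in_bed(bed, v.CHROM, v.POS - 1):
            continue
        alt = 0
        called = 0
        for g in v.genotypes:
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: non-diploid genotype; X input must be "
                    "female-only diploid calls"
                )
            for a in alleles:
                if a >= 0:
                    called += 1
                    alt += a > 0
        if called == 0 or (full_alleles - called) / full_alleles > max_missing:
            continue
        if alt > 0:
            any_alt = True
        if alt == 0 or alt == called:
            continue  # monomorphic among called samples
        kept += 1
        if called == m:
            acc[alt] += 1.0
        else:
            if called < m:
                continue  # cannot project up
            acc += _project_site(alt, called, m)
    if not contig_seen and region:
        raise ValueError(f"region {region!r} not found in {vcf_path}")
    if kept == 0:
        if seen == 0 or not any_alt:
            logger.warning(
                "no polymorphic biallelic SNPs in %s; returning empty SFS", vcf_path
            )
        else:
            raise ValueError("no sites survive filtering")
    lost = acc[0] + acc[m]
    if lost > 0:
        logger.info("projection dropped %.3g sites into monomorphic classes", lost)
    frac = kept / seen if seen else 1.0
    clen = CallableLength(raw_length, frac if frac > 0 else 1.0)
    s = SpectrumData(
        acc[1:m], m, folded=False, L=clen.adjusted_length, mu=mu,
        chrom_class=chrom_class,
    )
    if fold:
        s = fold_sfs(s)
    return s, clen
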