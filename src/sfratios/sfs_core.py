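"""Site frequency spectrum containers, folding, projection and ratios.

The SFS is the universal input of the method: a vector of counts of
polymorphic sites indexed by sample allele count.  Unfolded spectra are
indexed by derived-allele copies i = 1..n-1; folded spectra by minor-allele
copies i = 1..floor(n/2).  Counts are real-valued because hypergeometric
projection produces expectations rather than integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "SFS",
    "RatioSpectrum",
    "fold",
    "project",
    "watterson_theta",
    "make_ratios",
    "read_sfs",
    "write_sfs",
]

#: per-bin count below which the gaussian approximation to a Poisson count
#: becomes questionable
LOW_COUNT_THRESHOLD = 10.0


def _n_bins(n: int, folded: bool) -> int:
    return n // 2 if folded else n - 1


@dataclass(frozen=True)
class SFS:
    """A site frequency spectrum.

    Parameters
    ----------
    n : int
        Number of sampled chromosomes (>= 2).
    counts : array-like
        Per-bin polymorphic-site counts; length n-1 (unfolded) or
        floor(n/2) (folded).  Nonnegative, finite, real-valued.
    folded : bool
        Whether bins index minor-allele rather than derived-allele copies.
    label : str
        Free-text description.
    """

    n: int
    counts: np.ndarray
    folded: bool = False
    label: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        expected = _n_bins(self.n, self.folded)
        if counts.ndim != 1 or counts.size != expected:
            raise ValueError(
                f"{'folded' if self.folded else 'unfolded'} SFS with n={self.n} "
                f"requires {expected} bins, got {counts.size}"
            )
        if not np.all(np.isfinite(counts)):
            raise ValueError("SFS counts must be finite")
        if np.any(counts < 0):
            raise ValueError("SFS counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def segregating_sites(self) -> float:
        return float(self.counts.sum())

    def __eq__(self, other):
        if not isinstance(other, SFS):
            return NotImplemented
        return (
            self.n == other.n
            and self.folded == other.folded
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class RatioSpectrum:
    """Per-bin selected/neutral count ratios z_i with provenance.

    ``z[i]`` is selected/neutral wherever ``valid_mask[i]``; bins with a zero
    neutral count are masked invalid rather than imputed.  ``X`` and ``Y`` are
    the total selected and neutral polymorphic-site counts; ``theta_hat`` is
    Watterson's estimate from the neutral spectrum.
    """

    z: np.ndarray
    selected_counts: np.ndarray
    neutral_counts: np.ndarray
    n: int
    folded: bool
    valid_mask: np.ndarray
    X: float
    Y: float
    theta_hat: float
    low_count_bins: int = field(default=0, compare=False)


def fold(sfs: SFS) -> SFS:
    """Fold an unfolded SFS: bin i gains the count of bin n-i.

    The central bin i = n/2 (n even) maps to itself and is not doubled.
    Total site count is conserved exactly.
    """
    if sfs.folded:
        raise ValueError("SFS is already folded")
    n = sfs.n
    c = sfs.counts
    nb = n // 2
    out = np.empty(nb)
    for i in range(1, nb + 1):
        j = n - i
        if j != i:
            out[i - 1] = c[i - 1] + c[j - 1]
        else:  # center bin, n even
            out[i - 1] = c[i - 1]
    return SFS(n=n, counts=out, folded=True, label=sfs.label)


def project(sfs: SFS, m: int) -> SFS:
    """Expected hypergeometric projection of an unfolded SFS to sample size m.

    Bin j of the output receives ``sum_i counts[i] * P(j of m | i of n)``
    where P is hypergeometric; the monomorphic classes j = 0 and j = m are
    discarded, so projected total mass can be below the input total.
    """
    if sfs.folded:
        raise ValueError("projection requires an unfolded SFS")
    n = sfs.n
    if not (2 <= m < n):
        raise ValueError(f"target sample size must satisfy 2 <= m < n, got m={m}, n={n}")
    i = np.arange(1, n)  # derived copies in source
    j = np.arange(1, m)  # derived copies in target
    # P(j | i): drawing m chromosomes from n of which i carry the allele
    pmat = hypergeom.pmf(j[None, :], n, i[:, None], m)
    out = sfs.counts @ pmat
    return SFS(n=m, counts=out, folded=False, label=sfs.label)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(sfs: SFS) -> float:
    """Watterson's estimator theta_hat = S / a_n with a_n = sum_{i<n} 1/i.

    The same a_n applies whether the spectrum is stored folded or unfolded,
    since folding conserves the number of segregating sites.
    """
    s = sfs.segregating_sites
    if s <= 0:
        raise ValueError("Watterson's theta undefined for S = 0")
    return s / _harmonic(sfs.n)


def make_ratios(selected: SFS, neutral: SFS) -> RatioSpectrum:
    """Build the per-bin ratio spectrum z_i = selected_i / neutral_i.

    theta_hat is taken from the neutral spectrum (it estimates the neutral
    mutation parameter appearing in the ratio-density variance term).
    Bins where either count falls below 10 are counted and logged: there the
    gaussian approximation to the Poisson count ratio starts to degrade.
    """
    if selected.n != neutral.n:
        raise ValueError(f"sample sizes differ: {selected.n} vs {neutral.n}")
    if selected.folded != neutral.folded:
        raise ValueError("selected and neutral SFS must share the folded flag")
    sc = selected.counts
    nc = neutral.counts
    valid = nc > 0
    z = np.full(sc.shape, np.nan)
    z[valid] = sc[valid] / nc[valid]
    n_masked = int((~valid).sum())
    if n_masked:
        logger.warning("%d bin(s) with zero neutral count masked", n_masked)
    low = int(np.sum((sc < LOW_COUNT_THRESHOLD) | (nc < LOW_COUNT_THRESHOLD)))
    if low:
        logger.warning(
            "%d bin(s) have a count below %g; the gaussian approximation "
            "to the Poisson ratio may be poor there",
            low,
            LOW_COUNT_THRESHOLD,
        )
    return RatioSpectrum(
        z=z,
        selected_counts=sc.copy(),
        neutral_counts=nc.copy(),
        n=selected.n,
        folded=selected.folded,
        valid_mask=valid,
        X=float(sc.sum()),
        Y=float(nc.sum()),
        theta_hat=watterson_theta(neutral),
        low_count_bins=low,
    )


# ---------------------------------------------------------------------------
# plain-text IO
#
# Format: line 1  "#sfs n=<int> folded=<0|1> label=<text>"
#         line 2  whitespace-separated counts (decimals allowed)
# A bare single line of counts is also accepted, read as unfolded with
# n = len(counts) + 1.
# ---------------------------------------------------------------------------


def write_sfs(sfs: SFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sfs n={sfs.n} folded={int(sfs.folded)} label={sfs.label}\n")
        fh.write(" ".join(repr(float(c)) for c in sfs.counts) + "\n")


def read_sfs(path) -> SFS:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty SFS file")
    if lines[0].startswith("#sfs"):
        # label is the final field and may contain spaces
        toks = lines[0].split(maxsplit=3)
        fields = {}
        for tok in toks[1:]:
            if "=" not in tok:
                raise ValueError(f"{path}, line 1: malformed header token {tok!r}")
            k, _, v = tok.partition("=")
            fields[k] = v
        try:
            n = int(fields["n"])
            folded = bool(int(fields["folded"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}, line 1: malformed header ({exc})") from exc
        label = fields.get("label", "")
        if len(lines) < 2:
            raise ValueError(f"{path}, line 2: missing counts line")
        counts = _parse_counts(lines[1], path, lineno=2)
        try:
            return SFS(n=n, counts=counts, folded=folded, label=label)
        except ValueError as exc:
            raise ValueError(f"{path}, line 2: {exc}") from exc
    # bare counts: unfolded, n inferred
    counts = _parse_counts(lines[0], path, lineno=1)
    try:
        return SFS(n=len(counts) + 1, counts=counts, folded=False)
    except ValueError as exc:
        raise ValueError(f"{path}, line 1: {exc}") from exc


def _parse_counts(line: str, path, lineno: int) -> np.ndarray:
    try:
        return np.array([float(tok) for tok in line.split()])
    except ValueError as exc:
        raise ValueError(f"{path}, line {lineno}: unparseable count ({exc})") from exc
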