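import logging

import numpy as np
import pytest

from sfratios.prf_expectations import get_grid

logging.getLogger("sfratios").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid100f():
    """Folded expectation grid for n=100 (shared; expensive to build)."""
    return get_grid(100, True)


@pytest.fixture(scope="session")
def grid200f():
    return get_grid(200, True)


@pytest.fixture(scope="session")
def grid200u():
    return get_grid(200, False)


@pytest.fixture(scope="session")
def synthetic_vcf(tmp_path_factory):
    """A small synthetic VCF + reference + site-class table.

    'Selected' and short-intron sites are drawn from the same neutral
    allele-frequency distribution (p(i) ~ 1/i), so downstream fits should
    find rho ~ 1.  20 chromosomes (10 diploid samples), all sites fully
    genotyped, plus a couple of records exercising the filters.
    """
    rng = np.random.default_rng(20240917)
    tmp = tmp_path_factory.mktemp("vcfdata")
    chrom, length = "2L", 400_000
    seq = rng.choice(list("ACGT"), size=length)
    fa = tmp / "ref.fa"
    with open(fa, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for k in range(0, length, 70):
            fh.write(s[k : k + 70] + "\n")

    n_alleles = 20
    i_vals = np.arange(1, n_alleles)
    p = (1.0 / i_vals) / np.sum(1.0 / i_vals)
    n_sites = 1600
    positions = np.sort(rng.choice(np.arange(100, length - 100), size=n_sites, replace=False))
    lines = []
    classes = []
    for k, pos in enumerate(positions):
        ref = seq[pos - 1]  # VCF pos is 1-based
        alt = rng.choice([b for b in "ACGT" if b != ref])
        count = rng.choice(i_vals, p=p)
        alleles = np.zeros(n_alleles, int)
        alleles[rng.choice(n_alleles, size=count, replace=False)] = 1
        gts = "\t".join(f"{alleles[2*j]}/{alleles[2*j+1]}" for j in range(10))
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
        cls = "nonsynonymous" if k % 2 == 0 else "short_intron"
        classes.append(f"{chrom}\t{pos}\t{cls}")

    # filter fodder: a tri-allelic record, a 60%-called record (kept at the
    # default 50% threshold) and a 40%-called record (dropped)
    extra_pos = int(positions[-1]) + 50
    lines.append(
        f"{chrom}\t{extra_pos}\t.\t{seq[extra_pos-1]}\t"
        f"{','.join(b for b in 'ACGT' if b != seq[extra_pos-1])[:3]}\t.\tPASS\t.\tGT\t"
        + "\t".join(["0/1"] * 10)
    )
    extra2 = extra_pos + 50
    ref2 = seq[extra2 - 1]
    alt2 = "A" if ref2 != "A" else "C"
    lines.append(
        f"{chrom}\t{extra2}\t.\t{ref2}\t{alt2}\t.\tPASS\t.\tGT\t"
        + "\t".join(["./."] * 4 + ["0/1"] * 6)
    )
    extra3 = extra2 + 50
    ref3 = seq[extra3 - 1]
    alt3 = "A" if ref3 != "A" else "C"
    lines.append(
        f"{chrom}\t{extra3}\t.\t{ref3}\t{alt3}\t.\tPASS\t.\tGT\t"
        + "\t".join(["./."] * 6 + ["0/1"] * 4)
    )
    classes.append(f"{chrom}\t{extra_pos}\tnonsynonymous")
    classes.append(f"{chrom}\t{extra2}\tnonsynonymous")
    classes.append(f"{chrom}\t{extra3}\tnonsynonymous")

    vcf = tmp / "sites.vcf"
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={chrom},length={length}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"s{j}" for j in range(10))
        + "\n"
    )
    vcf.write_text(header + "\n".join(lines) + "\n")
    tsv = tmp / "classes.tsv"
    tsv.write_text("\n".join(classes) + "\n")
    return {"vcf": vcf, "fasta": fa, "classes": tsv, "chrom": chrom, "n_alleles": n_alleles}
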