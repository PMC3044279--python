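import numpy as np
import pytest

from strobehap import VariantTrack, synthesize_powerlaw_track


@pytest.fixture
def tiny_track():
    """Five sites at hand-picked kbp positions, with truth haplotypes."""
    pos = np.array([0, 3000, 6000, 9000, 12000])
    return VariantTrack(
        pos, 20000, truth=(np.zeros(5, dtype=np.int8), np.ones(5, dtype=np.int8))
    )


@pytest.fixture(scope="session")
def synth_track():
    """Moderate synthetic power-law track shared across simulation tests."""
    return synthesize_powerlaw_track(1_000_000, mean_gap=1000, seed=42)


def write_minimal_vcf(path, records, sample="S1"):
    """Write a minimal single-sample VCF. records: (chrom, pos1, ref, alts, gt)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = sorted({r[0] for r in records})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for chrom, pos1, ref, alts, gt in records:
        lines.append(
            f"{chrom}\t{pos1}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t{gt}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
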