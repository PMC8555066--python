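import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT1\tT2\tN1\tN2
"""


def _row(pos, qual, alt="G", t1=(40, 12), t2=(40, 12), n1=(40, 0), n2=(40, 0)):
    cells = []
    for dp, ad in (t1, t2, n1, n2):
        gt = "0/1" if ad > 0 else "0/0"
        cells.append(f"{gt}:{dp}:{dp - ad},{ad}")
    return f"chr1\t{pos}\t.\tA\t{alt}\t{qual}\tPASS\t.\tGT:DP:AD\t" + "\t".join(cells)


@pytest.fixture(scope="session")
def toy_vcf(tmp_path_factory):
    """Ten scripted records: four fail exactly one filter rule each.

    pos 200 fails quality (30 is not > 30); pos 300 fails depth (15 in T2 is
    not > 15); pos 400 falls outside the accessibility mask; pos 500 falls
    inside the low-complexity mask.  Of the six survivors, pos 700 is an
    inherited het (AF 0.5 in both normals); the other five are somatic.
    """
    rows = [
        _row(100, 60),
        _row(200, 30),
        _row(300, 60, t2=(15, 5)),
        _row(400, 60),
        _row(500, 60),
        _row(600, 60),
        _row(700, 60, t1=(60, 30), t2=(60, 30), n1=(60, 30), n2=(60, 30)),
        _row(800, 60),
        _row(900, 60),
        _row(1000, 60),
    ]
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    path.write_text(VCF_HEADER + "\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_masks():
    from metastrack.variant_io import RegionMask

    accessibility = RegionMask.from_intervals(
        [("chr1", 0, 350), ("chr1", 450, 2000)], keep_inside=True
    )
    lcr = RegionMask.from_intervals([("chr1", 480, 520)], keep_inside=False)
    return accessibility, lcr


@pytest.fixture(scope="session")
def small_cohort():
    """Noiseless 5-clone cohort used across phylogeny/subclone tests."""
    from metastrack import simulate as sim

    cfg = sim.SimulationConfig(
        seed=42, n_subclones=5, n_sites=6, depth_mean=None,
        purity_range=(1.0, 1.0), germline_het_spacing=None,
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Depth-60 cohort at the study's default conditions."""
    from metastrack import simulate as sim

    cfg = sim.SimulationConfig(
        seed=7, n_subclones=5, n_sites=6, germline_het_spacing=None
    )
    return sim.simulate_cohort(cfg)
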