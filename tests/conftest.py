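"""Shared fixtures: small simulation configs, handwritten file builders,
and a dict-backed genome for annotation tests."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import HealthCheck, settings

from hawmap import SimConfig
from hawmap.pipeline import run_simulation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class DictGenome:
    """Explicit-sequence genome store for hand-built test cases.

    Same 1-based-inclusive interface as the package's genome classes.
    """

    def __init__(self, sequences: dict):
        self._seqs = {k: v.upper() for k, v in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or end < start:
            raise ValueError(f"bad window {chrom}:{start}-{end}")
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def lengths(self) -> dict:
        return {k: len(v) for k, v in self._seqs.items()}


@pytest.fixture
def dict_genome_factory():
    return DictGenome


@pytest.fixture
def tiny_config():
    """A 2-chromosome config small enough for per-test simulation."""
    return SimConfig(
        chromosomes={"I": 1_000_000, "II": 800_000},
        hawaiian_density=1e-3,
        parental_variant_count=30,
        induced_mutation_count=40,
        genes_per_chromosome=6,
        causal_chrom="I",
        causal_pos=500_000,
        n_f2=200,
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """One cached end-to-end tiny simulation (seed 11)."""
    config = SimConfig(
        chromosomes={"I": 1_000_000, "II": 800_000},
        hawaiian_density=1e-3,
        parental_variant_count=30,
        induced_mutation_count=40,
        genes_per_chromosome=6,
        causal_chrom="I",
        causal_pos=500_000,
        n_f2=200,
    )
    return run_simulation(config, seed=11)


@pytest.fixture
def write_vcf(tmp_path):
    """Write a minimal single-sample VCF with AD and return its path."""

    def _write(records, name="calls.vcf", fmt="GT:AD:DP"):
        """records: iterable of (chrom, pos, ref, alt_field, sample_field).

        ``alt_field`` may hold comma-separated alts; ``sample_field`` is the
        raw sample column matching ``fmt``.
        """
        header = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=chrI,length=20000000>
            ##contig=<ID=chrII,length=20000000>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
            ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool
            """
        )
        body = "".join(
            f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\t{fmt}\t{s}\n"
            for c, p, r, a, s in records
        )
        path = tmp_path / name
        path.write_text(header + body)
        return str(path)

    return _write
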