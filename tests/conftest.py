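import pytest

from xdc import synthetic_data as sd


def make_gtf(tmp_path, lines, name="G1.gtf"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def gtf_line(chrom, start, end, strand, tid="t1", pid="p1", frame="0"):
    return (
        f"{chrom}\tsynth\tCDS\t{start}\t{end}\t.\t{strand}\t{frame}\t"
        f'gene_id "{tid}.g"; transcript_id "{tid}"; protein_id "{pid}";'
    )


@pytest.fixture
def small_bundle(tmp_path):
    """Two-genome synthetic bundle with planted enrichment, written to disk."""
    cfg = sd.SyntheticConfig(
        seed=11,
        n_genomes=2,
        n_proteins_per_genome=80,
        theta_domain=0.1,
        theta_disorder=0.05,
        frac_new_proteins=0.2,
        theta_new=0.3,
    )
    bundle = tmp_path / "bundle"
    sd.write_bundle(sd.generate_study(cfg), bundle, cfg)
    return bundle, cfg
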