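import os

import pytest

import pgsdesk as pk


@pytest.fixture(scope="session")
def small_cfg():
    """A structured cohort small enough for sub-second scoring runs."""
    return pk.SimulationConfig(
        n_populations=3, n_ref_per_pop=20, n_study=10, n_snps=300,
        fst=0.1, n_scores=4, variants_per_score=40,
        missing_rate=0.02, low_r2_rate=0.1,
        frac_absent=0.1, frac_palindromic=0.05, frac_complemented=0.2,
        frac_mismatch=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return pk.simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_cfg, small_panel):
    """Panel + study VCF + score files + written repository, as one bundle."""
    d = tmp_path_factory.mktemp("dataset")
    vcf = pk.write_study_vcf(small_panel, str(d / "study.vcf.gz"))
    sim = pk.simulate_scores(small_cfg, small_panel, str(d / "scores"))
    defs = [pk.parse_score_file(p) for p in sim.paths]
    repo = pk.merge_scores(defs)
    pk.write_repository(repo, str(d / "repo"))
    indexed = pk.load_repository(str(d / "repo"))
    return {
        "dir": d, "cfg": small_cfg, "panel": small_panel, "vcf": vcf,
        "sim": sim, "definitions": defs, "repo": repo, "indexed": indexed,
    }


def write_vcf_text(path, records, samples, contigs=(("1", 1000),), info_lines=()):
    """Write a tiny plain-text VCF for hand-built dosage fixtures."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="r2">\n')
        fh.write('##INFO=<ID=ER2,Number=1,Type=Float,Description="er2">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="typed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,Description="ds">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            fh.write("\t".join(rec) + "\n")
    return path


def bgzip_index(path):
    import pysam
    gz = path + ".gz"
    pysam.tabix_compress(path, gz, force=True)
    pysam.tabix_index(gz, preset="vcf", force=True)
    return gz
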