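import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def mutation_tsv(tmp_path):
    """Small hand-written mutation table in the synthdata TSV dialect."""
    text = (
        "clone_id\tgroup\tchrom\tpos\tref\talt\tgene\teffect\tallele_fraction\n"
        "c1\tmutant\tchr01\t100\tA\tT\tPGM1\tmissense\t1.0\n"
        "c1\tmutant\tchr02\t200\tC\tG\tALG9\tmissense\t1.0\n"
        "c1\tmutant\tchr03\t300\tG\tA\tYFG1\tsynonymous\t1.0\n"
        "c2\tmutant\tchr01\t150\tT\tC\tPGM1\tnonsense\t0.48\n"
        "c2\tmutant\tchr04\t400\tA\tC\tYFG2\tframeshift\t0.51\n"
        "c2\tmutant\tchr05\t500\tG\tT\tYFG3\tnoncoding\t0.97\n"
        "c3\twt\tchr06\t600\tC\tA\tYFG4\tmissense\t1.0\n"
        "c3\twt\tchr07\t700\tA\tG\tYFG5\tmissense\t1.0\n"
    )
    path = tmp_path / "mutations.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def snpeff_vcf(tmp_path):
    """Minimal single-sample VCF with SnpEff-style ANN annotations."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        "##contig=<ID=chrI,length=230218>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcloneA\n"
        "chrI\t1000\t.\tA\tT\t100\tPASS\t"
        "ANN=T|missense_variant|MODERATE|PGM1|PGM1|transcript|tx1|protein_coding\t"
        "GT:AD\t0/1:12,13\n"
        "chrI\t2000\t.\tC\tG\t100\tPASS\t"
        "ANN=G|stop_gained|HIGH|ALG9|ALG9|transcript|tx2|protein_coding\t"
        "GT:AD\t1/1:0,25\n"
        "chrI\t3000\t.\tG\tA\t100\tPASS\t"
        "ANN=A|conservative_inframe_deletion|MODERATE|YFG1|YFG1|transcript|tx3|protein_coding\t"
        "GT:AD\t0/1:10,10\n"
    )
    path = tmp_path / "clone.vcf"
    path.write_text(text)
    return path
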