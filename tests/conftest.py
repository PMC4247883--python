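import numpy as np
import pandas as pd
import pytest

from gpscore.data_model import GenotypeMatrix, Panel, SnpDef


@pytest.fixture
def small_panel():
    return Panel(
        (
            SnpDef("rs1", "GENE1", "A", "G", 0.1, reference_eaf=0.40),
            SnpDef("rs2", "GENE2", "C", "T", 0.2, reference_eaf=0.25),
            SnpDef("rs3", "GENE3", "T", "G", 0.3, reference_eaf=0.60),
        ),
        name="toy3",
    )


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        {
            "rs1": [0.0, 1.0, 2.0, 1.0],
            "rs2": [2.0, np.nan, 0.0, 1.0],
            "rs3": [1.0, 1.0, np.nan, 0.0],
        },
        index=pd.Index(["I1", "I2", "I3", "I4"], name="individual_id"),
    )
    return GenotypeMatrix(df)


@pytest.fixture
def genotype_tsv(tmp_path):
    text = (
        "individual_id\trs1\trs2\trs3\n"
        "I1\t0\t2\t1\n"
        "I2\t1\tNA\t1\n"
        "I3\t2\t0\tNA\n"
        "I4\t1\t1\t0\n"
    )
    path = tmp_path / "genotypes.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def paired_vcf(tmp_path):
    """VCF encoding the same genotypes as `genotype_tsv`.

    rs1 has the effect allele as ALT, rs2 and rs3 carry it as REF, so the
    reader must resolve orientation per record.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3\tI4\n"
    )
    # effect-allele counts: rs1 (EA=A=ALT): 0,1,2,1 ; rs2 (EA=C=REF): 2,.,0,1 ;
    # rs3 (EA=T=REF): 1,1,.,0
    body = (
        "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\t0/1\n"
        "1\t300\trs3\tT\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t./.\t1/1\n"
    )
    path = tmp_path / "genotypes.vcf"
    path.write_text(header + body)
    return path


@pytest.fixture
def phenotype_tsv(tmp_path):
    text = (
        "individual_id\tage\tsex\tsmoking\tactivity\tweight\theight\twaist\thip\n"
        "I1\t45\tmale\tnever\tlow\t70\t1.70\t90\t100\n"
        "I2\t52\tfemale\tcurrent\tnone\t86.7\t1.70\t104\t110\n"
        "I3\t33\tfemale\tformer\thigh\t55\t1.60\t70\t95\n"
        "I4\t60\tmale\tnever\tmedium\t90\t1.80\t100\t105\n"
    )
    path = tmp_path / "phenotypes.tsv"
    path.write_text(text)
    return path


def matrix_from_counts(n0: int, n1: int, n2: int, snp_id: str = "snp") -> GenotypeMatrix:
    """Expand genotype counts into a single-SNP matrix."""
    values = np.repeat([0.0, 1.0, 2.0], [n0, n1, n2])
    ids = pd.Index([f"I{i}" for i in range(len(values))], name="individual_id")
    return GenotypeMatrix(pd.DataFrame({snp_id: values}, index=ids))
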