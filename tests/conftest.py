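import pytest

from fasterz.tables_io import DivergenceRecord, PolymorphismRecord


def div(contig_id="c1", chrom="1", D_N=1.0, D_S=1.0, N=100.0, S=50.0, tree_dS=0.5,
        species=None):
    return DivergenceRecord(contig_id, chrom, D_N, D_S, N, S, tree_dS, species)


def poly(contig_id="c1", chrom="1", P_N=1, P_S=1, N=100.0, S=50.0, P_4D=0, L_4D=30):
    return PolymorphismRecord(contig_id, chrom, P_N, P_S, N, S, P_4D, L_4D)


@pytest.fixture
def six_species_newick():
    return ("((anser:25,anas:25):65,"
            "(numida:60,(pavo:45,(meleagris:30,phasianus:30):15):15):30):0;")
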