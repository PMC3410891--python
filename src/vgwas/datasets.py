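"""Packaged example data (synthetic) for demos and smoke tests.

The example dataset is simulated: 40 biallelic markers on two chromosomes
typed on 60 inbred lines, with the marker named ``causal`` controlling both
the mean and the standard deviation of ``trait1`` (means 0/0.3, SDs
0.5/1.5, LAF 0.5); ``trait2`` is pure noise with one missing value.
"""

from importlib import resources


def example_paths() -> dict:
    """Paths of the packaged example genotype/phenotype/gene files."""
    base = resources.files("vgwas") / "examples"
    return {
        "genotypes": str(base / "example.geno.tsv"),
        "phenotypes": str(base / "example.pheno.tsv"),
        "genes": str(base / "example.genes.bed"),
    }


def load_example():
    """Load the packaged example as (GenotypeMatrix, PhenotypeTable, genes)."""
    from .data import read_genotypes, read_intervals, read_phenotypes

    paths = example_paths()
    return (
        read_genotypes(paths["genotypes"]),
        read_phenotypes(paths["phenotypes"]),
        read_intervals(paths["genes"]),
    )
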