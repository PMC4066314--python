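"""jamkit: joint assembly and genetic mapping of outbred crosses.

A genotyping-by-sequencing toolkit that builds a high-density genetic
linkage map directly from low-coverage whole-genome reads of two outbred
parents and their F1 offspring, without a reference genome.  The pipeline
profiles k-mers, identifies allelic "SNPmer" pairs, assembles a k-mer
graph into marker scaffolds, jointly infers SNP phase and offspring
genotypes by incremental EM, and clusters markers into linkage groups.
Downstream modules test conserved macro-synteny against ancestral
linkage groups and date whole-genome duplications from Ks mixtures.
"""

__version__ = "0.1.0"

__all__ = [
    "assembly",
    "comparative",
    "genotyping",
    "kmers",
    "linkage",
    "pipeline",
    "simulate",
    "snpmers",
]


def __getattr__(name):  # lazy submodule access: jamkit.simulate etc.
    if name in __all__:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
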