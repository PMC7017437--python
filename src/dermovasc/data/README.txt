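Packaged data fixtures
======================

table1a.csv / table1b.csv
    Specimen tables for the two dermal-armour datasets (31 testudinatan
    shell cross-sections, 32 pseudosuchian osteoderm cross-sections):
    porosity fraction, lifestyle category, sampled region, ornamentation
    flag, geological age and collection number per plate.
    Yarasuchus deccanensis is carried in the pseudosuchian table with
    clade "Avemetatarsalia-outgroup" so it can be excluded by flag.

testudinata_reconstructed.nwk / pseudosuchia_reconstructed.nwk
    RECONSTRUCTED time-scaled phylogenies (branch lengths in Myr, one tip
    per taxon; conspecific plates are attached at run time with the 1-Myr
    split rule). Topologies follow the accepted relationships of the
    sampled taxa; node ages are rough literature-informed approximations,
    NOT published calibrations. Any quantity that depends on these branch
    lengths (K, lambda, phylogenetic ANOVA p-values on the in-package
    datasets) is illustrative only.
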