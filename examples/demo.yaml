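# Demo pipeline configuration: three simulated species sharing four
# ancestral LTR-RE families with species-specific copy numbers and burst
# ages.  Desk-scale read numbers; ploidy-proportional sampling.
seed: 7
stringency: high
substitution_rate: 2.0e-8
kappa: 2.0
read_length: 90
error_rate: 0.001
bin_width_mya: 0.5
min_overlap: 30
rt_read_cap: 200
n_bootstrap: 200
cut_fraction: 0.5
dating_family: chromoA

simulation:
  reads_per_diploid: 12000
  families:
    - {id: chromoA, superfamily: Gypsy, lineage: Chromovirus, ltr_length: 150, internal_length: 500}
    - {id: ogreA,   superfamily: Gypsy, lineage: Ogre/Tat,    ltr_length: 150, internal_length: 500}
    - {id: sireA,   superfamily: Copia, lineage: Maximus/SIRE, ltr_length: 150, internal_length: 500}
    - {id: aleA,    superfamily: Copia, lineage: AleII,        ltr_length: 150, internal_length: 500}
  species:
    - id: SPA
      ploidy: 2
      background_length: 6000
      families:
        - {master: chromoA, intact: 25, solo: 3, age_mya: 6.0}
        - {master: ogreA,   intact: 6,  solo: 1, age_mya: 8.0}
        - {master: sireA,   intact: 4,  solo: 0, age_mya: 2.0}
        - {master: aleA,    intact: 2,  solo: 0, age_mya: 3.0}
    - id: SPB
      ploidy: 2
      background_length: 6000
      families:
        - {master: chromoA, intact: 18, solo: 6, age_mya: 6.0}
        - {master: ogreA,   intact: 8,  solo: 0, age_mya: 8.0}
        - {master: sireA,   intact: 10, solo: 0, age_mya: 2.0}
        - {master: aleA,    intact: 3,  solo: 1, age_mya: 3.0}
    - id: SPC
      ploidy: 4
      background_length: 6000
      families:
        - {master: chromoA, intact: 22, solo: 2, age_mya: 6.0}
        - {master: ogreA,   intact: 7,  solo: 2, age_mya: 8.0}
        - {master: sireA,   intact: 5,  solo: 0, age_mya: 2.0}
        - {master: aleA,    intact: 4,  solo: 0, age_mya: 3.0}
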