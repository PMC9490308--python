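# Fixture specification for the 14-accession grass panel: per-marker ungapped
# sequence lengths (bp) and haplotype class letters for each accession at each
# of the four barcoding markers.  Accession order fixes the canonical letter
# assignment (A, B, C, ... by first appearance).  Accessions sharing a letter
# at a marker are generated sequence-identical at all gap-free alignment
# columns; different letters imply >= min_class_divergence substitutions.
markers: [ITS, matK, rbcL, trnL-F]
min_class_divergence: 1
accessions:
  - id: Agr_cris_cristatum
    genus: Agropyron
    species: cristatum
    infrataxon: cristatum
    infrataxon_rank: variety
    lengths: {ITS: 697, matK: 395, rbcL: 572, trnL-F: 463}
    haplotypes: {ITS: A, matK: A, rbcL: A, trnL-F: A}
  - id: Bro_inermis
    genus: Bromus
    species: inermis
    lengths: {ITS: 696, matK: 408, rbcL: 572, trnL-F: 473}
    haplotypes: {ITS: B, matK: B, rbcL: B, trnL-F: B}
  - id: Ely_dahuricus
    genus: Elymus
    species: dahuricus
    lengths: {ITS: 699, matK: 408, rbcL: 572, trnL-F: 473}
    haplotypes: {ITS: C, matK: C, rbcL: C, trnL-F: C}
  - id: Ely_sibiricus
    genus: Elymus
    species: sibiricus
    lengths: {ITS: 701, matK: 408, rbcL: 572, trnL-F: 470}
    haplotypes: {ITS: D, matK: D, rbcL: D, trnL-F: C}
  - id: Elt_repens
    genus: Elytrigia
    species: repens
    lengths: {ITS: 699, matK: 408, rbcL: 572, trnL-F: 470}
    haplotypes: {ITS: E, matK: E, rbcL: D, trnL-F: D}
  - id: Fes_rubra
    genus: Festuca
    species: rubra
    lengths: {ITS: 695, matK: 408, rbcL: 572, trnL-F: 444}
    haplotypes: {ITS: F, matK: F, rbcL: E, trnL-F: E}
  - id: Ley_chinensis
    genus: Leymus
    species: chinensis
    lengths: {ITS: 697, matK: 408, rbcL: 572, trnL-F: 455}
    haplotypes: {ITS: G, matK: G, rbcL: F, trnL-F: F}
  - id: Lol_per_MedalistGold
    genus: Lolium
    species: perenne
    infrataxon: Medalist Gold
    infrataxon_rank: cultivar
    lengths: {ITS: 696, matK: 408, rbcL: 572, trnL-F: 453}
    haplotypes: {ITS: H, matK: H, rbcL: G, trnL-F: G}
  - id: Agr_cris_pectiniforme
    genus: Agropyron
    species: cristatum
    infrataxon: pectiniforme
    infrataxon_rank: variety
    lengths: {ITS: 697, matK: 395, rbcL: 572, trnL-F: 458}
    haplotypes: {ITS: I, matK: I, rbcL: A, trnL-F: H}
  - id: Agr_mongolicum
    genus: Agropyron
    species: mongolicum
    lengths: {ITS: 682, matK: 408, rbcL: 572, trnL-F: 463}
    haplotypes: {ITS: J, matK: J, rbcL: A, trnL-F: A}
  - id: Agr_desertorum
    genus: Agropyron
    species: desertorum
    lengths: {ITS: 696, matK: 404, rbcL: 572, trnL-F: 463}
    haplotypes: {ITS: K, matK: K, rbcL: A, trnL-F: H}
  - id: Lol_per_Pickwick
    genus: Lolium
    species: perenne
    infrataxon: Pickwick
    infrataxon_rank: cultivar
    lengths: {ITS: 696, matK: 408, rbcL: 572, trnL-F: 453}
    haplotypes: {ITS: H, matK: H, rbcL: G, trnL-F: G}
  - id: Lol_per_Taya
    genus: Lolium
    species: perenne
    infrataxon: Taya
    infrataxon_rank: cultivar
    lengths: {ITS: 696, matK: 408, rbcL: 572, trnL-F: 453}
    haplotypes: {ITS: H, matK: H, rbcL: G, trnL-F: G}
  - id: Lol_per_Ascend
    genus: Lolium
    species: perenne
    infrataxon: Ascend
    infrataxon_rank: cultivar
    lengths: {ITS: 696, matK: 408, rbcL: 572, trnL-F: 453}
    haplotypes: {ITS: H, matK: H, rbcL: G, trnL-F: G}
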