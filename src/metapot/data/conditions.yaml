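# Canonical nutrient-condition library for soil-microbiome scope simulations.
#
# Five nested seed conditions: a basal medium of inorganic nutrients, metal
# ions, coenzymes and cofactors, contained in every other condition; two
# organic-carbon conditions (simple sugars entering glycolysis directly;
# complex soil organic matter); and two organic-nitrogen conditions (all 20
# genomically-encoded amino acids; the same minus the two sulfur-containing
# ones). Identifiers follow MetaCyc frame-id style. Compounds whose published
# identity is not available to this package are filled with flagged
# placeholder ids so that set sizes and nesting are exact on synthetic
# universes; every placeholder is listed under `placeholders`.
version: "1.0"
conditions:
  - name: basal_medium
    parent: null
    members:
      # inorganic carbon
      - HCO3
      - CARBON-DIOXIDE
      # inorganic nitrogen
      - NITROGEN-MOLECULE
      - AMMONIUM
      - NITRATE
      - NITRITE
      # inorganic sulfur
      - HS
      - SO3
      - S2O3
      - SULFATE
      # other inorganic chemicals
      - WATER
      - OXYGEN-MOLECULE
      - HYDROGEN-MOLECULE
      - PROTON
      - HYDROGEN-PEROXIDE
      - Pi
      - CL-
      - ARSENATE
      - OTHER-INORGANIC-UNSPEC-01
      # metal ions
      - MG+2
      - FE+2
      - NI+2
      - CO+2
      - CU+2
      - CPD-3
      # coenzymes and cofactors
      - NAD
      - FAD
      - CO-A
      - THIAMINE
      - COFACTOR-UNSPEC-01
      - COFACTOR-UNSPEC-02
      - COFACTOR-UNSPEC-03
      - COFACTOR-UNSPEC-04
      - COFACTOR-UNSPEC-05
      - COFACTOR-UNSPEC-06
      - COFACTOR-UNSPEC-07
      - COFACTOR-UNSPEC-08
      - COFACTOR-UNSPEC-09
      - COFACTOR-UNSPEC-10
      - COFACTOR-UNSPEC-11
      - COFACTOR-UNSPEC-12
      - COFACTOR-UNSPEC-13
      - COFACTOR-UNSPEC-14
    placeholders:
      - OTHER-INORGANIC-UNSPEC-01
      - COFACTOR-UNSPEC-01
      - COFACTOR-UNSPEC-02
      - COFACTOR-UNSPEC-03
      - COFACTOR-UNSPEC-04
      - COFACTOR-UNSPEC-05
      - COFACTOR-UNSPEC-06
      - COFACTOR-UNSPEC-07
      - COFACTOR-UNSPEC-08
      - COFACTOR-UNSPEC-09
      - COFACTOR-UNSPEC-10
      - COFACTOR-UNSPEC-11
      - COFACTOR-UNSPEC-12
      - COFACTOR-UNSPEC-13
      - COFACTOR-UNSPEC-14
  - name: simple_sugars
    parent: basal_medium
    members:
      - GLC
      - MALTOSE
      - GALACTOSE
      - L-ARABINOSE
      - SORBITOL
      - GLYCEROL
      - SIMPLE-SUGAR-UNSPEC-01
    placeholders:
      - SIMPLE-SUGAR-UNSPEC-01
  - name: complex_sugars
    parent: basal_medium
    members:
      - TREHALOSE
      - SUCROSE
      - RHAMNOSE
      - MANNITOL
      - XYLITOL
      - LINOLEIC-ACID
      - SPERMIDINE
      - COUMARATE
      - CHORISMATE
      - COMPLEX-CARBON-UNSPEC-01
      - COMPLEX-CARBON-UNSPEC-02
      - COMPLEX-CARBON-UNSPEC-03
      - COMPLEX-CARBON-UNSPEC-04
      - COMPLEX-CARBON-UNSPEC-05
      - COMPLEX-CARBON-UNSPEC-06
      - COMPLEX-CARBON-UNSPEC-07
      - COMPLEX-CARBON-UNSPEC-08
      - COMPLEX-CARBON-UNSPEC-09
      - COMPLEX-CARBON-UNSPEC-10
      - COMPLEX-CARBON-UNSPEC-11
      - COMPLEX-CARBON-UNSPEC-12
    placeholders:
      - COMPLEX-CARBON-UNSPEC-01
      - COMPLEX-CARBON-UNSPEC-02
      - COMPLEX-CARBON-UNSPEC-03
      - COMPLEX-CARBON-UNSPEC-04
      - COMPLEX-CARBON-UNSPEC-05
      - COMPLEX-CARBON-UNSPEC-06
      - COMPLEX-CARBON-UNSPEC-07
      - COMPLEX-CARBON-UNSPEC-08
      - COMPLEX-CARBON-UNSPEC-09
      - COMPLEX-CARBON-UNSPEC-10
      - COMPLEX-CARBON-UNSPEC-11
      - COMPLEX-CARBON-UNSPEC-12
  - name: non_sulfured_amino_acids
    parent: basal_medium
    members:
      - SER
      - PRO
      - VAL
      - THR
      - ILE
      - LEU
      - GLN
      - LYS
      - HIS
      - PHE
      - ARG
      - TYR
      - GLY
      - L-ALPHA-ALANINE
      - L-ASPARTATE
      - ASN
      - GLT
      - TRP
    placeholders: []
  - name: all_amino_acids
    parent: non_sulfured_amino_acids
    members:
      - CYS
      - MET
    placeholders: []
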