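# Default marker-gene configuration, version 1.
#
# Maps each biogeochemical conversion step to the KO "gene combination" whose
# summed abundance is taken as the step's genetic potential. Curated from KEGG
# pathway / BRITE membership for the canonical C/N/S conversion steps and the
# stress-adaptation themes profiled by this package. This file is data: it is
# versioned, overridable, and the engine's correctness claims do not depend on
# the particular curation.
#
# A KO may appear in more than one step only when every owning step is flagged
# ambiguous and carries a `clades` routing list (ordered, case-insensitive
# substring match against the gene's lineage ranks; first listed step whose
# clade list matches wins). Two such markers are shipped:
#   - aprA/dsrA-family (K00394/K00395/K11180/K11181): dissimilatory sulfate
#     reduction vs sulfide oxidation, routed by sulfate-reducer vs
#     sulfur-oxidizer phylogeny;
#   - amoA/pmoA-family (K10944/K10945/K10946): ammonia oxidation vs methane
#     oxidation, routed by nitrifier vs methanotroph phylogeny.
version: 1
cycles:
  carbon:
    - name: aerobic_respiration
      kos: [K02274, K02275, K02276]        # coxABC cytochrome c oxidase
      aerobicity: aerobic
    - name: aerobic_carbon_fixation
      kos: [K01601, K01602, K00855]        # RuBisCO large/small, PRK
      aerobicity: aerobic
    - name: anaerobic_carbon_fixation
      kos: [K15230, K15231, K00192, K00198]  # ATP-citrate lyase (rTCA), CODH/ACS
      aerobicity: anaerobic
    - name: fermentation
      kos: [K00016, K00625, K00925]        # ldh, pta, ackA
      aerobicity: anaerobic
    - name: co_oxidation
      kos: [K03518, K03519, K03520]        # coxSML CO dehydrogenase
      aerobicity: aerobic
    - name: methanogenesis
      kos: [K00399, K00401, K00402]        # mcrABG
      aerobicity: anaerobic
    - name: methane_oxidation
      kos: [K10944, K10945, K10946, K16157]  # pmoABC / mmoX
      aerobicity: aerobic
      ambiguous: true
      clades: [methylocystis, methylococc, methylomonas, methylosinus,
               methylocella, methylacidiphil, methylo]
  nitrogen:
    - name: nitrogen_fixation
      kos: [K02586, K02588, K02591]        # nifDHK
      aerobicity: n/a
    - name: nitrification
      kos: [K10944, K10945, K10946, K10535, K00370, K00371]  # amoABC, hao, nxrAB
      aerobicity: aerobic
      ambiguous: true
      clades: [nitrosomonas, nitrosospira, nitrosococcus, nitrosopumilus,
               nitrososphaera, nitrobacter, nitrospira, nitrolancea]
    - name: denitrification
      kos: [K00368, K15864, K04561, K02305, K00376]  # nirK, nirS, norBC, nosZ
      aerobicity: anaerobic
    - name: nitrogen_assimilation
      kos: [K01915, K00262, K00265, K00266]  # glnA (GS), gdhA, gltBD
      aerobicity: n/a
    - name: nitrogen_mineralization
      kos: [K01428, K01429, K01430]        # ureCBA urease
      aerobicity: n/a
  sulfur:
    - name: assimilatory_sulfate_reduction
      kos: [K00956, K00957, K00390, K00380, K00381]  # cysNDHJI
      aerobicity: n/a
    - name: dissimilatory_sulfate_reduction
      kos: [K00958, K00394, K00395, K11180, K11181]  # sat, aprAB, dsrAB
      aerobicity: anaerobic
      ambiguous: true
      clades: [desulfo, syntrophobacter, thermodesulfo, archaeoglobus,
               leptospirillum]
    - name: sulfide_oxidation
      kos: [K17218, K17229, K00394, K00395, K11180, K11181]  # sqr, fccB, reverse aprAB/dsrAB
      aerobicity: aerobic
      ambiguous: true
      clades: [chromati, chlorobi, thiohalobacter, thiobacillus, beggiatoa,
               allochromatium, sulfurimonas, thioalkalivibrio]
    - name: sulfur_oxidation_sox
      kos: [K17222, K17223, K17224, K17225, K17226, K17227]  # soxAXBCYZ
      aerobicity: aerobic
    - name: sulfur_mineralization
      kos: [K01130, K01760, K01011]        # arylsulfatase, metC, sseA
      aerobicity: n/a
  stress:dna_repair:
    - name: base_excision_repair
      kos: [K01246, K03648, K10563]        # alkA, ung, mutM
      aerobicity: n/a
    - name: nucleotide_excision_repair
      kos: [K03701, K03702, K03703]        # uvrABC
      aerobicity: n/a
    - name: mismatch_repair
      kos: [K03555, K03572]                # mutS, mutL
      aerobicity: n/a
    - name: homologous_recombination
      kos: [K03553, K03581, K03582]        # recA, recD, recB
      aerobicity: n/a
    - name: non_homologous_end_joining
      kos: [K10979, K01971]                # ku, ligD
      aerobicity: n/a
  stress:antioxidation:
    - name: superoxide_dismutase
      kos: [K04564, K04565]                # sodA/sodB, sodC
      aerobicity: n/a
    - name: catalase
      kos: [K03781, K03782]                # katE, katG
      aerobicity: n/a
    - name: peroxiredoxin
      kos: [K03386, K24119]                # ahpC, bcp-like
      aerobicity: n/a
  stress:cold_adaptation:
    - name: cold_shock_proteins
      kos: [K03704, K05592]                # cspA, deaD
      aerobicity: n/a
    - name: unsaturated_fatty_acid_biosynthesis
      kos: [K00507, K10255]                # delta-9 desaturase, fad2-like
      aerobicity: n/a
  stress:osmotic:
    - name: osmolyte_synthesis
      kos: [K00697, K01087, K00108, K00130]  # otsAB trehalose, betAB
      aerobicity: n/a
    - name: osmolyte_transport
      kos: [K02000, K02001, K02002]        # proVWX
      aerobicity: n/a
  stress:acid:
    - name: acid_resistance
      kos: [K01580, K00574]                # gadA/gadB, cfa
      aerobicity: n/a
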