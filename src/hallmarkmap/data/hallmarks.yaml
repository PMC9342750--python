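# Default cancer-hallmark definitions: ten hallmark categories, each a flat list
# of GO biological-process term labels.  `regulation: true` means the term is
# matched together with its three standard regulation forms ("regulation of X",
# "positive regulation of X", "negative regulation of X").  Compound printed
# entries are split into plain terms; "disease variant" (genome instability) is
# carried as a boolean annotation column, not a GO term.
hallmarks:
  - id: 1
    name: Sustained proliferative signaling
    terms:
      - {label: cell communication, regulation: true}
      - {label: signaling, regulation: true}
      - {label: signaling receptor activity, regulation: true}
  - id: 2
    name: Tissue invasion and metastasis
    terms:
      - {label: cell adhesion, regulation: true}
      - {label: cell motility, regulation: true}
      - {label: actin cytoskeleton organization, regulation: true}
      - {label: extracellular matrix organization, regulation: true}
      - {label: secretion, regulation: false}
      - {label: epithelial to mesenchymal transition, regulation: true}
  - id: 3
    name: Evasion of immune destruction
    terms:
      - {label: immune system process, regulation: false}
      - {label: innate immune response, regulation: true}
      - {label: adaptive immune response, regulation: true}
      - {label: antigen processing and presentation, regulation: true}
      - {label: autophagy, regulation: true}
      - {label: cellular senescence, regulation: false}
      - {label: cellular response to hypoxia, regulation: true}
      - {label: chemotaxis, regulation: true}
      - {label: chemokine mediated signaling pathway, regulation: true}
      - {label: chemokine production, regulation: true}
      - {label: myeloid cell activation, regulation: true}
      - {label: B cell activation, regulation: true}
      - {label: T cell activation, regulation: true}
  - id: 4
    name: Insensitivity to anti-growth signals
    terms:
      - {label: cell cycle, regulation: true}
      - {label: cell division, regulation: true}
      - {label: cell growth, regulation: true}
      - {label: cell population proliferation, regulation: true}
      - {label: protein catabolic process, regulation: true}
      - {label: protein folding, regulation: true}
      - {label: protein targeting, regulation: true}
      - {label: phosphatidylinositol 3-kinase signaling, regulation: true}
      - {label: TOR signaling, regulation: true}
      - {label: Wnt signaling pathway, regulation: true}
      - {label: signal transduction by p53 class mediator, regulation: true}
  - id: 5
    name: Genome instability
    terms:
      - {label: cellular response to DNA damage stimulus, regulation: true}
  - id: 6
    name: Evasion of apoptosis
    terms:
      - {label: cell death, regulation: true}
      - {label: cell aging, regulation: true}
      - {label: autophagy, regulation: true}
      - {label: apoptotic process, regulation: true}
      - {label: senescence, regulation: false}
      - {label: necrosis, regulation: false}
  - id: 7
    name: Inflammation
    terms:
      - {label: inflammatory response, regulation: true}
      - {label: I-kappaB kinase/NF-kappaB signaling, regulation: true}
      - {label: receptor signaling pathway via STAT, regulation: true}
      - {label: MAPK cascade, regulation: true}
      - {label: tumor necrosis factor mediated signaling pathway, regulation: true}
      - {label: macrophage activation, regulation: true}
      - {label: cellular response to cytokine stimulus, regulation: true}
  - id: 8
    name: Deregulating cellular energetics
    terms:
      - {label: gluconeogenesis, regulation: true}
      - {label: glycolytic process, regulation: true}
      - {label: canonical glycolysis, regulation: false}
      - {label: pyruvate oxidation, regulation: false}
      - {label: tricarboxylic acid cycle, regulation: false}
      - {label: oxidative phosphorylation, regulation: false}
      - {label: electron transport chain, regulation: false}
      - {label: ATP metabolic process, regulation: true}
      - {label: carbohydrate metabolic process, regulation: true}
      - {label: lipid metabolic process, regulation: true}
      - {label: one carbon metabolic process, regulation: false}
      - {label: choline metabolic process, regulation: false}
      - {label: cellular response to hypoxia, regulation: true}
      - {label: peroxisome proliferator activated receptor signaling pathway, regulation: true}
      - {label: energy homeostasis, regulation: false}
  - id: 9
    name: Sustained angiogenesis
    terms:
      - {label: angiogenesis, regulation: true}
      - {label: vascular endothelial growth factor signaling pathway, regulation: true}
  - id: 10
    name: Limitless replicative potential
    terms:
      - {label: DNA replication, regulation: true}
      - {label: chromosome organization, regulation: true}
      - {label: signal transduction by p53 class mediator, regulation: true}
      - {label: telomere maintenance, regulation: true}
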