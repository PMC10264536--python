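analyte_id,display_name,functional_group
TNFa,TNF-alpha,cytokine
IFNa,IFN-alpha,cytokine
IFNg,IFN-gamma,cytokine
IL1a,IL-1alpha,cytokine
IL1b,IL-1beta,cytokine
IL10,IL-10,cytokine
IL12p70,IL-12p70,cytokine
IL13,IL-13,cytokine
IL17A,IL-17A,cytokine
IL4,IL-4,cytokine
IL6,IL-6,cytokine
GMCSF,GM-CSF,cytokine
MCP1,MCP-1,chemokine
MIP1a,MIP-1alpha,chemokine
MIP1b,MIP-1beta,chemokine
IL8,IL-8,chemokine
IP10,IP-10,chemokine
BTLA,sBTLA,soluble_immune_checkpoint
sCD137,sCD137,soluble_immune_checkpoint
sCD27,sCD27,soluble_immune_checkpoint
sCD28,sCD28,soluble_immune_checkpoint
sCD80,sCD80,soluble_immune_checkpoint
sCTLA4,sCTLA-4,soluble_immune_checkpoint
sGITR,sGITR,soluble_immune_checkpoint
sHVEM,sHVEM,soluble_immune_checkpoint
sLAG3,sLAG-3,soluble_immune_checkpoint
sPD1,sPD-1,soluble_immune_checkpoint
sPDL1,sPD-L1,soluble_immune_checkpoint
sPDL2,sPD-L2,soluble_immune_checkpoint
sTIM3,sTIM-3,soluble_immune_checkpoint
sEselectin,sE-selectin,adhesion_molecule
sPselectin,sP-selectin,adhesion_molecule
sICAM1,sICAM-1,adhesion_molecule
IDO,IDO activity (kyn/trp),ido_activity
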