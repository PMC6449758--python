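// Cell-fate decision network for death-receptor (TNF) signalling.
// SYNTHETIC RECONSTRUCTION: the topology follows the published 2010
// death-receptor cell-fate logical model (Calzone et al., PLoS Comput
// Biol 6:e1000702), restricted to the TNF input, with added mRNA
// intermediate nodes (mFLIP, mXIAP, mROS) that delay NFkB-driven
// transcription/translation relative to protein-protein signalling.
// Rates are calibrated against population-level behaviour, not measured.
//
// Read-outs: Survival, Apoptosis, NonACD.  Sole input: TNF.

TNF {
  logic = TNF;
  rate_up = 0; rate_down = 0;          // pinned by the environment coupling
}

// --- receptor-proximal events (Micheau & Tschopp 2003 complex I/II) ---
TNFR {
  logic = TNF;
  rate_up = $k_sig; rate_down = $k_sig;
}
DISC {                                  // complex II / death-inducing complex
  logic = TNFR;
  rate_up = $k_disc; rate_down = $k_sig;
}

// --- survival branch: RIP1 -> IKK -> NFkB (Ea et al. 2006) ---
RIP1 {                                  // cleaved/inactivated by CASP8
  logic = TNFR & !CASP8;
  rate_up = $k_sig; rate_down = $k_sig;
}
RIP1ub {
  logic = RIP1;
  rate_up = $k_sig; rate_down = $k_sig;
}
IKK {
  logic = RIP1ub;
  rate_up = $k_sig; rate_down = $k_sig;
}
NFkB {                                  // shut down by effector caspases
  logic = IKK & !CASP3;
  rate_up = $k_sig; rate_down = $k_sig;
}

// --- NFkB transcriptional targets ---
cFLIP {                                 // caspase-8 inhibitor (Kreuz 2001)
  logic = NFkB;
  rate_up = $k_trans; rate_down = $k_sig;
}
BCL2 {
  logic = NFkB;
  rate_up = $k_trans; rate_down = $k_sig;
}
mXIAP {
  logic = NFkB;
  rate_up = $k_mrna; rate_down = $k_mrna_dec;
}
XIAP {                                  // neutralised by released SMAC
  logic = mXIAP & !SMAC;
  rate_up = $k_sig; rate_down = $k_sig;
}

// --- apoptosis branch: CASP8 -> MOMP -> CASP3 (Calzone 2010) ---
CASP8 {
  logic = DISC & !cFLIP;
  rate_up = $k_casp8; rate_down = $k_sig;
}
BAX {
  logic = CASP8 & !BCL2;
  rate_up = $k_casc; rate_down = $k_sig;
}
MOMP {
  logic = BAX;
  rate_up = $k_casc; rate_down = $k_sig;
}
SMAC {
  logic = MOMP;
  rate_up = $k_casc; rate_down = $k_sig;
}
CytC {
  logic = MOMP;
  rate_up = $k_casc; rate_down = $k_sig;
}
Apoptosome {
  logic = CytC & ATP & !XIAP;
  rate_up = $k_casc; rate_down = $k_sig;
}
CASP3 {
  logic = Apoptosome & !XIAP;
  rate_up = $k_casc; rate_down = $k_sig;
}

// --- non-apoptotic death branch: RIP1 kinase -> ROS -> MPT (Festjens 2006) ---
RIP1K {
  logic = RIP1;
  rate_up = $k_sig; rate_down = $k_sig;
}
mROS {                                  // transcription of ROS-generating machinery
  logic = RIP1K | MPT;
  rate_up = $k_mrna; rate_down = $k_mrna_dec;
}
ROS {                                   // quenched by NFkB-induced antioxidants
  logic = mROS & !NFkB;
  rate_up = $k_ros; rate_down = $k_sig;
}
MPT {                                   // mitochondrial permeability transition
  logic = ROS & !BCL2;
  rate_up = $k_ros; rate_down = $k_sig;
}
ATP {
  logic = !MPT;
  rate_up = $k_sig; rate_down = $k_sig;
}

// --- read-outs ---
Survival {                              // proliferative read-out: on in naive
  logic = NFkB | !DISC;                 // cells, NFkB-dependent once the death
  rate_up = $k_sig; rate_down = $k_sig; // receptor pathway is engaged
}
Apoptosis {
  logic = CASP3;
  rate_up = $k_sig; rate_down = $k_sig;
}
NonACD {
  logic = !ATP;
  rate_up = $k_sig; rate_down = $k_sig;
}
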