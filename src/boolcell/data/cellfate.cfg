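// Configuration for the reconstructed TNF cell-fate network.
// SYNTHETIC RECONSTRUCTION: rate values are calibrated so that a
// sustained-TNF ensemble reproduces the reported population behaviour
// (heterogeneous fates, ~half of a treated population committing to
// death within 24 h, ~20% apoptosis without NFkB activation, apoptosis
// committing faster than NonACD).  Units: 1/min.

$k_sig      = 0.1;    // generic protein-level signalling step (~10 min)
$k_disc     = 0.05;   // death-complex assembly
$k_casp8    = 0.035;   // caspase-8 activation at the DISC (rate-limiting)
$k_casc     = 0.08;   // downstream apoptotic cascade steps
$k_trans    = 0.04;   // NFkB-driven protein induction (BCL2)
$k_mrna     = 0.03;   // transcription+translation of mRNA nodes (slow)
$k_mrna_dec = 0.01;   // mRNA turnover
$k_ros      = 0.02;   // ROS accumulation / permeability transition

// Input node: pinned by the coupling layer, off by default.
TNF.is_input = TRUE;

// Initial condition: healthy proliferating cell (ATP available).
ATP.istate = 1;
Survival.istate = 1;

// Everything except the three fate read-outs is internal.
TNFR.is_internal = TRUE;
DISC.is_internal = TRUE;
RIP1.is_internal = TRUE;
RIP1ub.is_internal = TRUE;
IKK.is_internal = TRUE;
NFkB.is_internal = TRUE;
cFLIP.is_internal = TRUE;
BCL2.is_internal = TRUE;
mXIAP.is_internal = TRUE;
XIAP.is_internal = TRUE;
CASP8.is_internal = TRUE;
BAX.is_internal = TRUE;
MOMP.is_internal = TRUE;
SMAC.is_internal = TRUE;
CytC.is_internal = TRUE;
Apoptosome.is_internal = TRUE;
CASP3.is_internal = TRUE;
RIP1K.is_internal = TRUE;
mROS.is_internal = TRUE;
ROS.is_internal = TRUE;
MPT.is_internal = TRUE;
ATP.is_internal = TRUE;
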