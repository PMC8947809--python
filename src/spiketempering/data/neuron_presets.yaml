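# Reference LIF parameter sets (mV, ms, pF, nS).
cuba:
  C_m: 200.0
  g_l: 2000.0
  E_l: -50.0
  v_th: -50.0
  v_reset: -55.1
  tau_ref: 10.0
  synapse_kind: current
  tau_s: 10.0
coba:
  C_m: 250.0
  g_l: 25.0
  E_l: -65.0
  v_th: -50.0
  v_reset: -65.0
  tau_ref: 3.0
  synapse_kind: conductance
  E_exc: 0.0
  E_inh: -80.0
  tau_exc: 2.0
  tau_inh: 3.0
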