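{
  "dH_id_kJ": 24.84,
  "dS_id_J_per_K": 45.59,
  "Thm_K": 297.6,
  "source": "synthetic: back-derived as the composition-averaged difference between the packaged apparent solution functions and the published mixing functions for sulfamethazine in MeCN + EtOH; not a measured literature value. Override with literature ideal-dissolution functions where available."
}
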