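sample_label,dHfus_kJ_mol,sd_dHfus,Tfus_K,sd_Tfus
original,33.41,0.3,468.9,0.5
recrystallized_MeCN,33.57,0.3,467.9,0.5
recrystallized_MeCN_EtOH_0.50,32.27,0.3,467.9,0.5
recrystallized_EtOH,33.27,0.3,469.7,0.5
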