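# Parameter reference

Config/CLI names map to the published calibration symbols as below.

| name | symbol | value | unit |
|---|---|---|---|
| `r_BDNF` | r_BDNF | 0.3 | s^-1 |
| `k_fB` | k_fB | 0.0015 | mM/s |
| `K_CaMKII_BDNF_syn` | K_CaMKII,BDNF | 0.0073 | mM |
| `K_trans` | K_trans | 0.03 | mM |
| `K_dB` | K_dB | 0.6 | mM |
| `k_dBDNF` | k_dBDNF | 0.00066 | mM/s |
| `k_basalp_creb` | k_basalp_creb | 3.2e-06 | s^-1 |
| `k_dphos_creb` | k_dphos_creb | 9.6e-05 | s^-1 |
| `k_phos_creb` | k_phos_creb | 0.004 | s^-1 |
| `K_CREB_BDNF` | K_CREB_BDNF | 2 | mM |
| `CREB_total` | CREB_total | 0.085 | mM |
| `k_basal_cebp` | k_basal_cebp | 0.016 | s^-1 |
| `k_f_cebp` | k_f_cebp | 2.2 | s^-1 |
| `k_d_cebp` | k_d_cebp | 0.0057 | mM/s |
| `K_CREB_CEBP` | K_CREB_CEBP | 0.19 | mM |
| `CEBP_max` | CEBP_max | 0.23 | mM |
| `K_cebp` | K_cebp | 0.076 | mM |
| `tau_cebp` | tau_cebp | 3000 | s |
| `k_b_MeCP2` | k_b_MeCP2 | 1.6e-07 | mM/s |
| `k_f_bdnf` | k_f_bdnf | 0.00016 | mM/s |
| `K_a_bdnf` | K_a_bdnf | 3.2 | mM |
| `k_degb` | k_degb | 4.5e-05 | mM/s |
| `K_db` | K_db | 0.6 | mM |
| `k_f_EMeCP2` | k_f_EMeCP2 | 0.34 | mM |
| `E_MeCP2_max` | [E_MeCP2]_max | 5 | mM |
| `tau_E_MeCP2` | tau_E_MeCP2 | 14400 | s |
| `k_f_comp` | k_f_comp | 4.5 | mM |
| `k_d_comp` | k_d_comp | 0.0067 | mM |
| `B_Sin3a_basal` | [B_Sin3a]_basal | 1 | mM |
| `B_HDAC2_basal` | [B_HDAC2]_basal | 1 | mM |
| `E_comp_max` | [I_Comp]_max | 5 | mM |
| `tau_comp` | tau_Comp | 36000 | s |
| `r_CaMKII` | r_CaMKII | 0.15 | s^-1 |
| `k_basalp_CaMKII` | k_basalp_CaMKII | 3.6e-06 | mM/s |
| `k_dphos_CaMKII` | k_dphos_CaMKII | 0.00011 | s^-1 |
| `pCaMKII_total` | pCaMKII_total | 0.085 | mM |
| `k_CaMKII_B` | k_CaMKII_B | 5.3e-05 | mM/s |
| `K_CaMKII_BDNF` | K_CaMKII_BDNF | 0.28 | mM |
| `k_CaMKII_F` | k_CaMKII_F | 4.1e-05 | mM/s |
| `K_CaMKII_feed` | K_CaMKII_feed | 0.03 | mM |
| `r_sin3a` | r_sin3a | 30000 | mM^-1 |
| `k_f_Sin3a` | k_f_Sin3a | 0.25 | mM^-2 |
| `tau_sin3a` | tau_sina | 50000 | s |
| `B_Sin3a_max` | [B_Sin3a]_max | 5 | mM |
| `k_f_HDAC2` | k_f_HDAC2 | 0.25 | mM^-2 |
| `B_HDAC2_max` | [B_HDAC2]_max | 5 | mM |
| `tau_HDAC2` | tau_HDAC2 | 125000 | s |
| `k_f_MeCP2` | k_f_MeCP2 | 0.25 | mM^-2 |
| `B_MeCP2_max` | [B_MeCP2]_max | 5 | mM |
| `k_d_MeCP2` | k_d_MeCP2 | 4 | mM |
| `K_pCaMKII_MeCP2` | K_pCaMKII_MeCP2 | 0.011 | mM |
| `tau_MeCP2` | tau_MeCP2 | 10000 | s |
| `k_f_tag` | k_f_tag | 0.5 | mM^-1 s^-1 |
| `k_d_tag` | k_d_tag | 0.03 | s^-1 |
| `tau_Tag` | tau_Tag | 5 | s |
| `k_f_tif1` | k_f_tif1 | 0.00011 | mM^-1 s^-1 |
| `k_d_tif1` | k_d_tif1 | 3e-05 | s^-1 |
| `k_f_tif2` | k_f_tif2 | 2.4e-05 | mM^-1 s^-1 |
| `k_d_tif2` | k_d_tif2 | 6e-05 | s^-1 |
| `k_basal_GPROD` | k_basal_GROP | 0.0004 | mM/s |
| `k_f_GPROD` | k_f_GROD | 7.5 | mM/s |
| `k_d_GPROD` | k_d_GROD | 0.05 | s^-1 |
| `K_tif1` | K_tif1 | 1 | mM |
| `tau_GPROD` | tau_GPROD | 2000 | s |
| `K_tif2` | K_tif2 | 1 | mM |
| `k_basal_p` | k_basal_p | 0.48 | mM |
| `k_f_w` | k_f_w | 1680 | mM |
| `K_p` | K_p | 13.3 | mM |
| `k_d_w` | k_d_w | 0.08 | s^-1 |
| `Tag_basal` | [tag]_basal | 0.1 | mM |
| `GPROD_basal` | [GPROD]_basal | 0.12 | mM |
| `K_w_pp` | K_w_pp | 0.9 | mM |
| `tau_p` | tau_p | 25000 | s |
| `tau_pp` | tau_pp | 750000 | s |
| `k_f_pp` | k_f_pp | 0.8 | mM |
| `B_MeCP2_basal` | [B_MeCP2]_basal | 0.98 | mM |
| `stim_amplitude` | stim | 0.03 | mM/s |
| `stim_duration` | stim duration | 60 | s |
| `ani_level` | ANI | 0.8 | 1 |
| `disruptor_duration` | disruptor duration | 21600 | s |
| `consolidation_threshold` | W threshold | 2 | 1 |
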