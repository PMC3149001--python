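# Calibrated kinetic parameter table (uM and s units).
# One set for all experiments; estimated by staged trust-region
# least squares against the printed validation features.
k_ca_in: 0.0045000000000000005
k_ca_in_rcpt: 0.006468618000905271
k_ca_leak: 0.00167
k_ca_out: 0.042077111044312276
k_ca_pump: 0.04767824484572003
k_ca_rel: 0.5
k_cam1_b: 11.637484330802746
k_cam1_f: 6.0
k_cam2_b: 7.992254434843493
k_cam2_f: 5.639768038466904
k_cgmp_deg: 0.015835027513109893
k_cgmp_prod: 0.10023282415546812
k_cpi_bind: 42.40343693703188
k_cpi_dephos: 0.003016707220712433
k_cpi_phos: 0.009486541164496582
k_cpi_unbind: 0.06089241521036333
k_dag_deg: 0.01
k_dag_prod: 0.056433260357667464
k_dag_prod_g: 0.1301328703099566
k_enos_act_his: 3.4649338336365565
k_enos_act_vegf: 12.654341247734513
k_enos_bind: 10.0
k_enos_unbind: 0.01
k_enosp_deact: 0.3284048691005588
k_erk_dephos: 0.02
k_erk_phos: 0.165
k_g12_act: 0.048228282401565375
k_g12_deact: 0.01
k_gef_act: 0.043561775507946744
k_gef_deact: 0.01
k_gq_act: 19.738445906770057
k_gq_act_his: 4.4
k_gq_deact: 0.1
k_h1_bind: 20.0
k_h1_des: 0.00019648478320755366
k_h1_unbind: 0.005
k_ip3_deg: 0.03
k_ip3_prod: 0.2195706613932477
k_ip3_prod_g: 0.012849505088792547
k_mek_dephos: 0.02
k_mek_phos: 0.132
k_mlck_bind: 10.0
k_mlck_cat: 0.1075447253332645
k_mlck_cat2: 0.07507086974245844
k_mlck_phos: 0.043324529231567994
k_mlck_unbind: 0.45
k_mlckp_cat: 0.019740541126980416
k_mlckp_cat2: 0.013623838859374475
k_mlckp_dephos: 0.002
k_mycp_cat: 0.5451412437279938
k_mycp_cat2: 0.4171105865616593
k_mypt_dephos: 0.0023677405071671482
k_mypt_phos: 0.017296907839247942
k_no_deg: 0.1
k_no_prod: 0.5792503016735705
k_par1_bind: 20.0
k_par1_des: 0.0008638869243003493
k_par1_rec: 0.0001
k_par1_unbind: 0.0001
k_pkc_act: 0.021381801656922668
k_pkc_deact: 0.0025963452940818664
k_pkg_act: 0.01415713330989282
k_pkg_deact: 0.021660538020403106
k_plcb_act: 1.9389792709364915
k_plcb_deact: 0.1
k_plcg_act: 20.0
k_plcg_deact: 0.1
k_raf_act: 0.133
k_raf_act_pkg: 0.002
k_raf_deact: 0.02
k_ras_act: 1.0057076570648482
k_ras_gap: 0.02
k_rho_act: 0.1368616207024382
k_rho_gap: 0.0011726657920921163
k_rock_act_pkg: 0.3569963984883238
k_rock_act_rho: 0.037823696186979415
k_rock_cat: 0.08145165022116377
k_rock_cat2: 0.10657417361306365
k_rock_close: 0.01135227574567963
k_rock_deact: 0.007906744481876228
k_rock_open: 0.66230144122412
k_sgc_act: 0.38272207438076855
k_sgc_deact: 0.06450494642904513
k_thr_clear: 0.0001
k_vegf_bind: 22.659890203338147
k_vegf_unbind: 0.16000000000000003
k_vr2_int: 0.0045
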