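rule_id,compound_class,polarity,kind,value,series_count,tolerance,weight
flav_rda_169,flavonoids,negative,diagnostic_ion,169.0661,1,0.01,2
flav_aglycone_269,flavonoids,negative,diagnostic_ion,269.0455,1,0.01,2
flav_glca_loss,flavonoids,negative,neutral_loss,176.03209,1,0.01,1
flav_glc_loss,flavonoids,negative,neutral_loss,162.05282,1,0.01,1
flav_ch3_loss,flavonoids,negative,neutral_loss,15.02348,1,0.01,1
flav_h2o_loss,flavonoids,negative,neutral_loss,18.01056,1,0.01,1
flav_co_loss,flavonoids,negative,neutral_loss,27.99491,1,0.01,1
flav_ch2o_loss,flavonoids,negative,neutral_loss,30.01057,1,0.01,1
flav_o_loss,flavonoids,negative,neutral_loss,15.99491,1,0.01,1
terp_iridoid_179,terpenoids,negative,diagnostic_ion,179.0565,1,0.01,2
terp_iridoid_89,terpenoids,negative,diagnostic_ion,89.0249,1,0.01,2
terp_ch2o_loss,terpenoids,negative,neutral_loss,30.01057,1,0.01,1
terp_o_loss,terpenoids,negative,neutral_loss,15.99491,1,0.01,1
terp_glc_loss,terpenoids,negative,neutral_loss,162.05282,1,0.01,1
terp_arabinose_loss,terpenoids,negative,neutral_loss,146.05791,1,0.01,1
terp_sesq_ch2_ladder,terpenoids,positive,serial_loss,14.01565,3,0.01,2
terp_h2o_loss_pos,terpenoids,positive,neutral_loss,18.01056,1,0.01,1
terp_ursane_249,terpenoids,positive,diagnostic_ion,249.1352,1,0.01,2
terp_ursane_203,terpenoids,positive,diagnostic_ion,203.1791,1,0.01,2
terp_ursane_191,terpenoids,positive,diagnostic_ion,191.1795,1,0.01,2
pp_ch3_loss,phenylpropanoids,positive,neutral_loss,15.02348,1,0.01,1
pp_ch2o_loss,phenylpropanoids,positive,neutral_loss,30.01057,1,0.01,1
pp_h2o_loss,phenylpropanoids,positive,neutral_loss,18.01056,1,0.01,1
pp_co2_loss,phenylpropanoids,positive,neutral_loss,43.98983,1,0.01,1
pp_ch2o_ladder,phenylpropanoids,positive,serial_loss,30.01057,2,0.01,2
pp_glc_loss,phenylpropanoids,positive,neutral_loss,162.05282,1,0.01,1
pp_rutinose_loss,phenylpropanoids,positive,neutral_loss,308.11073,1,0.01,1
alk_ring_c_160,alkaloids,positive,diagnostic_ion,160.0757,1,0.01,2
alk_ring_c_170,alkaloids,positive,diagnostic_ion,170.0966,1,0.01,2
alk_ring_c_144,alkaloids,positive,diagnostic_ion,144.0808,1,0.01,2
alk_ch4o_loss,alkaloids,positive,neutral_loss,32.02621,1,0.01,1
aq_ch3_ladder,anthraquinones,negative,serial_loss,15.02348,2,0.01,2
aq_ch3_loss,anthraquinones,negative,neutral_loss,15.02348,1,0.01,1
aq_co_loss,anthraquinones,negative,neutral_loss,27.99491,1,0.01,1
aq_o_loss,anthraquinones,negative,neutral_loss,15.99491,1,0.01,1
aq_glc_loss,anthraquinones,negative,neutral_loss,162.05282,1,0.01,1
peg_caffeoyl_179,phenylethanoid glycosides,negative,diagnostic_ion,179.0351,1,0.01,2
peg_caffeoyl_135,phenylethanoid glycosides,negative,diagnostic_ion,135.0452,1,0.01,2
peg_glc_loss,phenylethanoid glycosides,negative,neutral_loss,162.05282,1,0.01,1
oligo_ch2o_ladder,oligosaccharides,negative,serial_loss,30.01057,2,0.01,2
oligo_glc_loss,oligosaccharides,negative,neutral_loss,162.05282,1,0.01,1
oligo_feruloyl_loss,oligosaccharides,negative,neutral_loss,176.04734,1,0.01,1
pa_co2_loss,phenolic acids,negative,neutral_loss,43.98983,1,0.01,1
pa_h2o_loss,phenolic acids,negative,neutral_loss,18.01056,1,0.01,1
pa_co_loss,phenolic acids,negative,neutral_loss,27.99491,1,0.01,1
xan_h2o_loss,xanthones,positive,neutral_loss,18.01056,1,0.01,1
xan_co_loss,xanthones,positive,neutral_loss,27.99491,1,0.01,1
xan_ch3_loss,xanthones,positive,neutral_loss,15.02348,1,0.01,1
flav_rda_pos_169,flavonoids,positive,diagnostic_ion,169.0649,1,0.01,2
flav_rda_pos_123,flavonoids,positive,diagnostic_ion,123.0080,1,0.01,2
aq_pos_ch3_ladder,anthraquinones,positive,serial_loss,15.02348,2,0.01,2
aq_pos_ch3_loss,anthraquinones,positive,neutral_loss,15.02348,1,0.01,1
aq_pos_co_loss,anthraquinones,positive,neutral_loss,27.99491,1,0.01,1
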