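subject_id,true_disposition,true_shape,noise_sd,drawn_change,start_level
S001,integrated_functional,monotonic_decrease,0.5,-29.369706,53.50751
S002,integrated_functional,discontinuous_other,0.5,-13.860729,50.267117
S003,integrated_functional,discontinuous_other,0.5,-46.29722,54.903096
S004,integrated_functional,monotonic_decrease,0.5,33.581612,57.439844
S005,integrated_functional,v_shape,0.5,6.06719,56.182364
S006,integrated_functional,v_shape,0.5,-82.430971,45.56725
S007,integrated_dysfunctional,monotonic_increase,0.5,81.408726,42.431767
S008,integrated_dysfunctional,v_shape,0.5,220.876188,35.732099
S009,integrated_dysfunctional,discontinuous_other,0.5,-178.017852,43.29571
S010,integrated_dysfunctional,monotonic_decrease,0.5,19.083656,43.883145
S011,integrated_dysfunctional,v_shape,0.5,111.446852,40.040255
S012,integrated_dysfunctional,v_shape,0.5,186.41587,38.552738
S013,disintegrated_functional,plateau,0.5,-108.455761,25.972854
S014,disintegrated_functional,v_shape,0.5,43.788748,30.480841
S015,disintegrated_functional,v_shape,0.5,-128.257871,27.107185
S016,disintegrated_dysfunctional,discontinuous_other,0.5,-33.315746,29.075605
S017,disintegrated_dysfunctional,v_shape,0.5,93.744766,20.232278
S018,disintegrated_dysfunctional,plateau,0.5,-54.510479,29.083534
S019,disintegrated_dysfunctional,monotonic_increase,0.5,201.687958,25.702121
S020,disintegrated_dysfunctional,discontinuous_other,0.5,-157.044888,33.433228
S021,disintegrated_dysfunctional,monotonic_decrease,0.5,-26.90873,32.814975
S022,disintegrated_dysfunctional,v_shape,0.5,155.608943,32.767251
S023,disintegrated_dysfunctional,monotonic_decrease,0.5,69.039098,28.585118
S024,disintegrated_dysfunctional,discontinuous_other,0.5,62.36406,29.295596
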