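dataset,cell_id,automated,observer1,observer2
DataSet1,2,3.520,3.513,3.431
DataSet1,19,2.786,2.675,2.883
DataSet1,25,4.129,3.590,3.947
DataSet1,32,3.728,3.367,3.613
DataSet2,10,3.816,3.474,3.466
DataSet2,32,3.028,2.633,2.454
DataSet2,24,3.748,3.534,3.575
DataSet2,31,3.572,3.389,3.159
DataSet3,3,2.006,2.189,2.646
DataSet3,39,1.678,1.897,2.426
DataSet3,34,2.099,2.202,2.006
DataSet3,46,4.314,4.543,4.313
DataSet3,33,3.671,3.624,2.944
DataSet3,48,3.304,3.519,3.194
DataSet4,3,2.738,2.446,2.916
DataSet4,47,2.797,2.706,3.206
DataSet4,17,2.531,2.628,2.044
DataSet4,54,3.004,2.559,1.965
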