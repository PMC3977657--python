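# cdqc columnar export: final_processed [delta_epsilon]
200.000 1.731925
201.000 0.228229
202.000 -1.186587
203.000 -2.526709
204.000 -3.746929
205.000 -4.823569
206.000 -5.685877
207.000 -6.258943
208.000 -6.493048
209.000 -6.403464
210.000 -6.046335
211.000 -5.518008
212.000 -4.898356
213.000 -4.323081
214.000 -3.913772
215.000 -3.743367
216.000 -3.811591
217.000 -4.116103
218.000 -4.585911
219.000 -5.117076
220.000 -5.598377
221.000 -5.939803
222.000 -6.053166
223.000 -5.889404
224.000 -5.458572
225.000 -4.815566
226.000 -4.043473
227.000 -3.241060
228.000 -2.472372
229.000 -1.791467
230.000 -1.230194
231.000 -0.815369
232.000 -0.521073
233.000 -0.316528
234.000 -0.177527
235.000 -0.087957
236.000 -0.045492
237.000 -0.021080
238.000 -0.017353
239.000 -0.007486
240.000 -0.010945
241.000 -0.012482
242.000 -0.003229
243.000 0.007399
244.000 0.011835
245.000 0.007745
246.000 0.017971
247.000 0.012751
248.000 0.004129
249.000 -0.001353
250.000 -0.013021
251.000 -0.008844
252.000 -0.000352
253.000 0.000470
254.000 -0.016820
255.000 -0.020599
256.000 -0.004907
257.000 0.005460
258.000 0.000487
259.000 0.003527
260.000 0.007579
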