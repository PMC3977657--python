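# cdqc columnar export: raw_sample [millidegrees]
200.000 25.684199 339.914197
201.000 5.579754 336.636257
202.000 -14.599702 333.812983
203.000 -32.913845 331.000976
204.000 -49.870195 326.307142
205.000 -64.596755 324.175503
206.000 -76.265724 320.558056
207.000 -84.006751 318.528655
208.000 -87.545209 315.548023
209.000 -86.443219 312.125368
210.000 -81.256647 311.033104
211.000 -73.956214 307.891512
212.000 -65.665254 305.645243
213.000 -57.818179 303.184968
214.000 -52.124501 301.286318
215.000 -49.367467 299.803612
216.000 -50.512933 297.550606
217.000 -54.704480 295.941363
218.000 -61.508391 294.163050
219.000 -68.855011 292.917857
220.000 -75.526243 290.429192
221.000 -80.310050 288.270184
222.000 -81.510037 288.012675
223.000 -79.354195 285.843744
224.000 -73.340614 285.154833
225.000 -64.538812 283.432636
226.000 -54.131175 281.871983
227.000 -42.656366 280.859650
228.000 -32.211926 280.457582
229.000 -22.762143 279.364557
230.000 -15.021655 277.250077
231.000 -9.182620 276.228351
232.000 -4.943529 275.661088
233.000 -2.262380 273.715052
234.000 -0.522204 273.357957
235.000 0.631986 272.269142
236.000 0.926864 271.565335
237.000 1.305166 270.152262
238.000 1.496426 268.967643
239.000 1.639570 267.951039
240.000 1.952151 267.684327
241.000 1.702753 267.298362
242.000 1.810110 266.693833
243.000 2.143299 267.148722
244.000 1.808212 266.098672
245.000 2.022327 264.455075
246.000 1.683221 264.524321
247.000 1.823896 263.584238
248.000 1.669991 263.104969
249.000 1.787192 262.820385
250.000 2.018061 262.538247
251.000 1.499536 261.579539
252.000 1.926885 261.820403
253.000 1.882547 260.274880
254.000 1.711170 260.423747
255.000 1.535788 261.310818
256.000 1.834426 259.730945
257.000 1.709101 259.958831
258.000 1.856535 258.925591
259.000 1.809370 258.822036
260.000 2.120356 258.168725
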