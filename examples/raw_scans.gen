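# cdqc .gen-style export
#SCANS 3
200.000 25.684199 25.809495 26.118566 339.914197 340.273060 340.459958
201.000 5.579754 5.181399 5.429975 336.636257 336.425524 336.310997
202.000 -14.599702 -14.227273 -14.345314 333.812983 333.626341 333.764615
203.000 -32.913845 -32.802869 -32.625610 331.000976 329.714822 330.471924
204.000 -49.870195 -49.630908 -49.816994 326.307142 327.331026 327.190752
205.000 -64.596755 -64.546978 -64.406849 324.175503 324.521733 324.257356
206.000 -76.265724 -76.336595 -76.371322 320.558056 321.261593 321.226537
207.000 -84.006751 -83.872760 -84.410314 318.528655 318.148182 319.308843
208.000 -87.545209 -87.713216 -87.749095 315.548023 315.840549 315.570019
209.000 -86.443219 -86.478699 -86.020563 312.125368 312.886485 312.887280
210.000 -81.256647 -81.613557 -81.083509 311.033104 311.036729 310.192192
211.000 -73.956214 -73.995915 -73.953857 307.891512 307.278310 307.677881
212.000 -65.665254 -65.685454 -65.486754 305.645243 305.744389 305.289957
213.000 -57.818179 -57.464492 -57.299233 303.184968 302.724438 303.275446
214.000 -52.124501 -51.985056 -52.162020 301.286318 300.865929 301.578119
215.000 -49.367467 -49.761061 -49.645845 299.803612 300.271598 299.756814
216.000 -50.512933 -50.744534 -50.412753 297.550606 298.092820 297.670799
217.000 -54.704480 -54.779874 -54.921498 295.941363 295.417292 295.394264
218.000 -61.508391 -61.255316 -61.423965 294.163050 293.230837 294.432181
219.000 -68.855011 -68.487373 -68.919408 292.917857 290.775262 292.627233
220.000 -75.526243 -75.068589 -75.583846 290.429192 290.328837 290.520761
221.000 -80.310050 -80.165299 -79.966685 288.270184 290.218821 288.682155
222.000 -81.510037 -81.799299 -81.583275 288.012675 287.696506 287.753278
223.000 -79.354195 -79.648219 -79.093022 285.843744 285.729702 286.103475
224.000 -73.340614 -73.214461 -73.678038 285.154833 284.830076 283.873473
225.000 -64.538812 -64.625053 -64.472208 283.432636 282.460468 283.206957
226.000 -54.131175 -53.975079 -54.060653 281.871983 281.788890 282.068569
227.000 -42.656366 -42.876180 -42.997524 280.859650 280.735001 280.235415
228.000 -32.211926 -32.146203 -32.293676 280.457582 279.439025 279.576997
229.000 -22.762143 -22.551446 -22.831466 279.364557 278.721470 277.598656
230.000 -15.021655 -15.086395 -14.934624 277.250077 277.387709 277.883479
231.000 -9.182620 -9.303653 -9.537205 276.228351 276.482418 276.772230
232.000 -4.943529 -5.283737 -5.070480 275.661088 274.778782 274.996709
233.000 -2.262380 -2.577620 -2.339517 273.715052 274.586790 274.319609
234.000 -0.522204 -0.534806 -0.503079 273.357957 274.005891 271.986461
235.000 0.631986 0.637173 0.848481 272.269142 271.796999 271.703900
236.000 0.926864 1.617917 1.371954 271.565335 270.964533 271.261491
237.000 1.305166 1.620643 1.862068 270.152262 271.236838 270.032880
238.000 1.496426 1.957514 1.730065 268.967643 269.666754 270.119625
239.000 1.639570 1.739160 1.699831 267.951039 269.689441 269.986179
240.000 1.952151 1.635208 1.827425 267.684327 268.021751 267.654711
241.000 1.702753 1.690825 1.932348 267.298362 268.255223 267.108968
242.000 1.810110 1.740698 1.921057 266.693833 266.906172 266.958153
243.000 2.143299 2.309147 1.666575 267.148722 266.309221 266.985664
244.000 1.808212 1.715188 1.897563 266.098672 266.328034 264.934488
245.000 2.022327 2.042522 1.920470 264.455075 264.755235 265.060639
246.000 1.683221 1.689359 2.373440 264.524321 263.879906 265.261116
247.000 1.823896 2.051298 2.240352 263.584238 263.563495 262.961897
248.000 1.669991 1.936986 1.689347 263.104969 263.473318 262.606616
249.000 1.787192 1.823671 1.797522 262.820385 261.944843 262.515919
250.000 2.018061 1.841847 1.557311 262.538247 262.547397 261.968367
251.000 1.499536 1.714042 1.726859 261.579539 261.479783 262.155469
252.000 1.926885 1.929214 1.903121 261.820403 261.862383 261.409307
253.000 1.882547 1.744003 2.076171 260.274880 259.648719 259.958368
254.000 1.711170 1.584879 1.684183 260.423747 260.027295 260.678283
255.000 1.535788 1.569412 1.694171 261.310818 259.168747 259.723212
256.000 1.834426 1.854518 1.390542 259.730945 259.206291 260.256629
257.000 1.709101 2.130818 1.782467 259.958831 259.366056 258.928430
258.000 1.856535 1.841998 1.597517 258.925591 258.790217 258.561523
259.000 1.809370 1.781272 1.699112 258.822036 258.404959 258.802213
260.000 2.120356 1.857165 1.624628 258.168725 258.117524 258.578580
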