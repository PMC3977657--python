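##TITLE=example final processed spectrum
##JCAMP-DX=4.24
##DATA TYPE=final_processed
##XUNITS=NANOMETERS
##YUNITS=delta_epsilon
##XFACTOR=1
##YFACTOR=1
##FIRSTX=200.000000
##LASTX=260.000000
##NPOINTS=61
##XYDATA=(X++(Y..Y))
200.000000 1.7319253 0.22822899 -1.1865866 -2.5267092 -3.7469286 -4.8235695
206.000000 -5.6858766 -6.2589429 -6.4930482 -6.4034635 -6.0463349 -5.5180083
212.000000 -4.8983559 -4.323081 -3.9137715 -3.7433669 -3.8115906 -4.1161033
218.000000 -4.5859114 -5.117076 -5.5983769 -5.9398032 -6.0531658 -5.8894037
224.000000 -5.4585717 -4.815566 -4.0434734 -3.2410597 -2.4723724 -1.7914666
230.000000 -1.2301944 -0.81536902 -0.52107283 -0.31652808 -0.17752742 -0.087956599
236.000000 -0.045491729 -0.021080052 -0.017352815 -0.0074857812 -0.010945328 -0.01248178
242.000000 -0.0032288507 0.0073986083 0.011835218 0.0077448787 0.017970819 0.012750844
248.000000 0.0041291016 -0.001352576 -0.013020519 -0.0088439974 -0.00035166327 0.00047040405
254.000000 -0.016819558 -0.020599301 -0.0049068436 0.0054595345 0.00048697955 0.0035271781
260.000000 0.0075794953
##END=
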