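2
name=H2
H  0.000000 0.000000 0.000000
H  0.620000 0.000000 0.000000
3
name=H2O
O  0.000000 0.000000 0.000000
H  0.970000 0.000000 0.000000
H -0.242800 0.939100 0.000000
4
name=NH3
N  0.000000 0.000000 0.000000
H  0.961500 0.000000 -0.340000
H -0.480700 0.832700 -0.340000
H -0.480700 -0.832700 -0.340000
5
name=CH4
C  0.000000 0.000000 0.000000
H  0.617800 0.617800 0.617800
H -0.617800 -0.617800 0.617800
H -0.617800 0.617800 -0.617800
H  0.617800 -0.617800 -0.617800
4
name=C2H2
C  0.000000 0.000000 0.000000
C  1.520000 0.000000 0.000000
H -1.070000 0.000000 0.000000
H  2.590000 0.000000 0.000000
3
name=CO2
C  0.000000 0.000000 0.000000
O  1.420000 0.000000 0.000000
O -1.420000 0.000000 0.000000
4
name=H2CO
C  0.000000 0.000000 0.000000
O  1.420000 0.000000 0.000000
H -0.535000 0.926600 0.000000
H -0.535000 -0.926600 0.000000
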