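window,year,rainfall_mm,temperature_c,ndvi
January-April,2000,291,23,0.641
January-April,2005,486.788,23.918,0.636
January-April,2010,567.659,23.788,0.635
January-April,2015,542.209,24.277,0.583
January-April,2020,889.444,22.92,0.66
June-September,2000,27.013,25.05,0.381
June-September,2005,24.905,24.028,0.416
June-September,2010,25.889,24.181,0.422
June-September,2015,30.412,24.76,0.424
June-September,2020,33.763,23.853,0.475
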