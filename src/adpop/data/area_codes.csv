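area_code,region
204,MB
226,ON
236,BC
249,ON
250,BC
289,ON
306,SK
343,ON
365,ON
403,AB
416,ON
418,QC
431,MB
437,ON
438,QC
450,QC
506,NB
514,QC
519,ON
548,ON
579,QC
581,QC
587,AB
604,BC
613,ON
639,SK
647,ON
705,ON
709,NL
778,BC
780,AB
782,NS
807,ON
819,QC
825,AB
867,YT
873,QC
902,NS
905,ON
206,WA
212,NY
213,CA
312,IL
404,GA
415,CA
503,OR
617,MA
702,NV
718,NY
808,HI
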