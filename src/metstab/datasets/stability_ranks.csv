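genotype,trait,r_asi,r_y,ssi
Dh 86,IOD15F,21,23.0,44.0
Dh 86,IOD21F,23,23.0,46.0
Dh 86,IOD15L,30,24.0,54.0
Dh 86,IOD21L,24,23.0,47.0
Girnar 3,IOD15F,3,21.0,24.0
Girnar 3,IOD21F,24,22.0,46.0
Girnar 3,IOD15L,1,19.0,20.0
Girnar 3,IOD21L,18,19.0,37.0
PBS 15044,IOD15F,12,11.0,23.0
PBS 15044,IOD21F,10,8.0,18.0
PBS 15044,IOD15L,8,16.5,24.5
PBS 15044,IOD21L,7,17.0,24.0
PBS 16004,IOD15F,11,5.0,16.0
PBS 16004,IOD21F,16,7.0,23.0
PBS 16004,IOD15L,15,4.0,19.0
PBS 16004,IOD21L,9,8.0,17.0
PBS 16013,IOD15F,14,6.5,20.5
PBS 16013,IOD21F,18,5.0,23.0
PBS 16013,IOD15L,2,14.5,16.5
PBS 16013,IOD21L,17,13.0,30.0
PBS 16015,IOD15F,6,2.5,8.5
PBS 16015,IOD21F,7,1.5,8.5
PBS 16015,IOD15L,12,4.0,16.0
PBS 16015,IOD21L,4,2.0,6.0
PBS 16016,IOD15F,9,8.0,17.0
PBS 16016,IOD21F,6,6.0,12.0
PBS 16016,IOD15L,14,4.0,18.0
PBS 16016,IOD21L,5,2.0,7.0
PBS 16017,IOD15F,2,9.0,11.0
PBS 16017,IOD21F,4,14.0,18.0
PBS 16017,IOD15L,17,8.0,25.0
PBS 16017,IOD21L,10,6.5,16.5
PBS 16020,IOD15F,17,10.0,27.0
PBS 16020,IOD21F,15,13.0,28.0
PBS 16020,IOD15L,16,16.5,32.5
PBS 16020,IOD21L,19,15.0,34.0
PBS 16021,IOD15F,5,2.5,7.5
PBS 16021,IOD21F,13,4.0,17.0
PBS 16021,IOD15L,11,4.0,15.0
PBS 16021,IOD21L,2,4.0,6.0
PBS 16024,IOD15F,30,22.0,52.0
PBS 16024,IOD21F,30,21.0,51.0
PBS 16024,IOD15L,24,20.0,44.0
PBS 16024,IOD21L,22,20.0,42.0
PBS 16025,IOD15F,26,29.0,55.0
PBS 16025,IOD21F,28,29.0,57.0
PBS 16025,IOD15L,26,28.0,54.0
PBS 16025,IOD21L,27,27.0,54.0
PBS 16026,IOD15F,4,14.0,18.0
PBS 16026,IOD21F,14,12.0,26.0
PBS 16026,IOD15L,7,9.0,16.0
PBS 16026,IOD21L,13,6.5,19.5
PBS 16027,IOD15F,24,28.0,52.0
PBS 16027,IOD21F,22,27.0,49.0
PBS 16027,IOD15L,18,29.0,47.0
PBS 16027,IOD21L,11,30.5,41.5
PBS 16028,IOD15F,16,32.0,48.0
PBS 16028,IOD21F,8,32.0,40.0
PBS 16028,IOD15L,6,31.0,37.0
PBS 16028,IOD21L,20,28.0,48.0
PBS 16029,IOD15F,29,30.0,59.0
PBS 16029,IOD21F,12,30.0,42.0
PBS 16029,IOD15L,22,30.0,52.0
PBS 16029,IOD21L,25,30.5,55.5
PBS 16031,IOD15F,22,13.0,35.0
PBS 16031,IOD21F,19,10.0,29.0
PBS 16031,IOD15L,9,4.0,13.0
PBS 16031,IOD21L,6,5.0,11.0
PBS 16032,IOD15F,28,26.0,54.0
PBS 16032,IOD21F,25,28.0,53.0
PBS 16032,IOD15L,29,27.0,56.0
PBS 16032,IOD21L,14,32.0,46.0
PBS 16035,IOD15F,1,16.0,17.0
PBS 16035,IOD21F,1,15.0,16.0
PBS 16035,IOD15L,20,11.0,31.0
PBS 16035,IOD21L,26,12.0,38.0
PBS 16037,IOD15F,15,6.5,21.5
PBS 16037,IOD21F,11,11.0,22.0
PBS 16037,IOD15L,13,4.0,17.0
PBS 16037,IOD21L,12,9.0,21.0
PBS 16038,IOD15F,19,12.0,31.0
PBS 16038,IOD21F,21,9.0,30.0
PBS 16038,IOD15L,4,12.5,16.5
PBS 16038,IOD21L,8,10.0,18.0
PBS 16039,IOD15F,23,15.0,38.0
PBS 16039,IOD21F,26,17.0,43.0
PBS 16039,IOD15L,23,14.5,37.5
PBS 16039,IOD21L,23,14.0,37.0
PBS 16041,IOD15F,7,2.5,9.5
PBS 16041,IOD21F,9,1.5,10.5
PBS 16041,IOD15L,10,4.0,14.0
PBS 16041,IOD21L,3,2.0,5.0
PBS 16042,IOD15F,10,18.0,28.0
PBS 16042,IOD21F,20,18.0,38.0
PBS 16042,IOD15L,3,12.5,15.5
PBS 16042,IOD21L,1,16.0,17.0
PBS 16044,IOD15F,13,31.0,44.0
PBS 16044,IOD21F,3,31.0,34.0
PBS 16044,IOD15L,27,32.0,59.0
PBS 16044,IOD21L,21,29.0,50.0
PBS 16045,IOD15F,8,2.5,10.5
PBS 16045,IOD21F,5,3.0,8.0
PBS 16045,IOD15L,5,10.0,15.0
PBS 16045,IOD21L,15,11.0,26.0
PBS 16046,IOD15F,25,20.0,45.0
PBS 16046,IOD21F,2,20.0,22.0
PBS 16046,IOD15L,28,22.0,50.0
PBS 16046,IOD21L,32,21.0,53.0
PBS 16047,IOD15F,31,25.0,56.0
PBS 16047,IOD21F,31,25.0,56.0
PBS 16047,IOD15L,25,26.0,51.0
PBS 16047,IOD21L,28,25.0,53.0
PBS 16051,IOD15F,27,24.0,51.0
PBS 16051,IOD21F,29,24.0,53.0
PBS 16051,IOD15L,32,23.0,55.0
PBS 16051,IOD21L,31,24.0,55.0
PBS 16052,IOD15F,32,27.0,59.0
PBS 16052,IOD21F,32,26.0,58.0
PBS 16052,IOD15L,31,25.0,56.0
PBS 16052,IOD21L,29,26.0,55.0
PBS 16053,IOD15F,20,19.0,39.0
PBS 16053,IOD21F,27,19.0,46.0
PBS 16053,IOD15L,19,21.0,40.0
PBS 16053,IOD21L,30,22.0,52.0
TPG 41,IOD15F,18,17.0,35.0
TPG 41,IOD21F,17,16.0,33.0
TPG 41,IOD15L,21,18.0,39.0
TPG 41,IOD21L,16,18.0,34.0
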